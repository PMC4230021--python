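"""End-to-end workflow glue: regression -> combination -> FDR -> regions.

Each stage consumes and produces :class:`~betameth.tables.SiteResult`
lists, so the staged command-line workflow and a single in-memory run
give byte-identical answers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import combine
from .betabinom import test_site
from .regions import DMRegion, call_dm_sites, filter_regions, merge_regions, \
    summarize_region
from .tables import CountTable, DesignMatrix, SiteResult


def _group_levels(totals: np.ndarray, meths: np.ndarray, in_b: np.ndarray
                  ) -> tuple[float, float]:
    ta, tb = totals[~in_b].sum(), totals[in_b].sum()
    la = float(meths[~in_b].sum() / ta) if ta > 0 else float("nan")
    lb = float(meths[in_b].sum() / tb) if tb > 0 else float("nan")
    return la, lb


def run_regression(counts: CountTable, design: DesignMatrix,
                   test_factor: str) -> list[SiteResult]:
    """Per-site beta-binomial LRT of ``test_factor``; untestable sites
    get p_raw = NA but keep whatever pooled levels are computable."""
    design.check_samples(counts)
    j = design.factor_columns(test_factor)[0]
    in_b = design.X[:, j] == 1
    results = []
    for r in range(counts.n_sites):
        t, m = counts.totals[r], counts.meths[r]
        la, lb = _group_levels(t, m, in_b)
        p = test_site(design, test_factor, t, m).p_raw
        results.append(SiteResult(key=counts.sites[r], p_raw=p,
                                  meth_a=la, meth_b=lb))
    return results


def run_adjust(results: Sequence[SiteResult], window_bp: int = 200,
               max_dist: int = 200) -> list[SiteResult]:
    """Fill p_combined (weighted-Z over the window) and p_adjusted (BH)."""
    chroms = np.array([r.key.chrom for r in results])
    positions = np.array([r.key.pos for r in results], dtype=np.int64)
    p_raw = np.array([r.p_raw for r in results], dtype=float)
    p_comb = combine.adjust_all(chroms, positions, p_raw,
                                window_bp=window_bp, max_dist=max_dist)
    p_adj = combine.bh_fdr(p_comb)
    out = []
    for r, pc, pa in zip(results, p_comb, p_adj):
        out.append(SiteResult(key=r.key, p_raw=r.p_raw, p_combined=float(pc),
                              p_adjusted=float(pa), meth_a=r.meth_a,
                              meth_b=r.meth_b))
    return out


def run_merge(results: Sequence[SiteResult], counts: CountTable | None = None,
              design: DesignMatrix | None = None, test_factor: str = "case",
              fdr_cutoff: float = 0.01, max_gap: int = 200,
              min_cpgs: int = 1, min_diff: float = 0.0) -> list[DMRegion]:
    """Call DM sites, merge into regions, summarize and filter.

    With ``counts``/``design`` absent, per-region summaries fall back to
    the per-site pooled levels already stored in the results (sufficient
    for min_meth_diff; log_odds then uses level-implied odds without
    coverage weights across sites).
    """
    chroms = np.array([r.key.chrom for r in results])
    positions = np.array([r.key.pos for r in results], dtype=np.int64)
    p_adj = np.array([r.p_adjusted for r in results], dtype=float)
    testable = ~np.isnan(np.array([r.p_raw for r in results], dtype=float))
    dm = call_dm_sites(p_adj, cutoff=fdr_cutoff)
    regs = merge_regions(chroms, positions, dm, testable, max_gap=max_gap)
    for reg in regs:
        if counts is not None and design is not None:
            summarize_region(reg, counts, design, test_factor, testable=testable)
        else:
            _summarize_from_levels(reg, results, testable)
    if min_cpgs > 1 or min_diff > 0.0:
        regs = filter_regions(regs, min_cpgs=min_cpgs, min_diff=min_diff)
    return regs


def _summarize_from_levels(reg: DMRegion, results: Sequence[SiteResult],
                           testable: np.ndarray) -> None:
    import math

    la, lb, diffs = [], [], []
    for i in range(reg.first_site, reg.last_site + 1):
        if not testable[i]:
            continue
        a, b = results[i].meth_a, results[i].meth_b
        if math.isnan(a) or math.isnan(b):
            continue
        la.append(a)
        lb.append(b)
        diffs.append(abs(a - b))
    if not diffs:
        return
    pa = min(max(float(np.mean(la)), 1e-6), 1 - 1e-6)
    pb = min(max(float(np.mean(lb)), 1e-6), 1 - 1e-6)
    reg.log_odds = math.log(pa * (1 - pb) / (pb * (1 - pa)))
    reg.min_meth_diff = float(min(diffs))


def run_pipeline(counts: CountTable, design: DesignMatrix, test_factor: str,
                 *, window_bp: int = 200, max_dist: int = 200,
                 fdr_cutoff: float = 0.01, max_gap: int = 200,
                 min_cpgs: int = 1, min_diff: float = 0.0
                 ) -> tuple[list[SiteResult], list[DMRegion]]:
    """Single-shot library pipeline equal to the staged CLI workflow."""
    results = run_regression(counts, design, test_factor)
    results = run_adjust(results, window_bp=window_bp, max_dist=max_dist)
    regs = run_merge(results, counts, design, test_factor,
                     fdr_cutoff=fdr_cutoff, max_gap=max_gap,
                     min_cpgs=min_cpgs, min_diff=min_diff)
    return results, regs
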