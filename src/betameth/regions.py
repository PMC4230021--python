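"""DM-site calling and merging into differentially methylated regions.

Sites whose FDR-adjusted combined p-value falls strictly below the cutoff
(default 0.01) are called DM. Consecutive DM sites on one chromosome with
no more than ``max_gap`` bp between neighbors are merged into one region;
tested-but-not-significant sites interior to the span count toward
``n_cpgs`` without breaking the run, so n_sig/n_cpgs measures how strongly
the region is dominated by DM sites.

Region summaries use coverage-pooled group methylation levels:
``log_odds`` is the log odds ratio of the two groups' pooled levels over
the whole region (with +0.5/+1 Laplace smoothing of pooled counts) and
``min_meth_diff`` the smallest absolute per-site pooled group difference
among member sites covered in both groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tables import CountTable, DesignMatrix


@dataclass
class DMRegion:
    """A differentially methylated region (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    n_sig: int
    log_odds: float = float("nan")
    min_meth_diff: float = float("nan")
    first_site: int = -1     # index range of member (tested) sites in the
    last_site: int = -1      # originating table, inclusive


def call_dm_sites(adjusted_p, cutoff: float = 0.01) -> np.ndarray:
    """DM flag per site: adjusted p strictly below the cutoff; NA is never
    DM."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    p = np.asarray(adjusted_p, dtype=float)
    with np.errstate(invalid="ignore"):
        return (p < cutoff) & ~np.isnan(p)


def merge_regions(chroms, positions, dm_flags, testable, max_gap: int = 200
                  ) -> list[DMRegion]:
    """Merge runs of DM sites (inter-site distance <= max_gap) into regions.

    Sites must be sorted by (chrom, pos). A region spans its first to last
    DM member site; singleton DM sites yield single-CpG regions. Summary
    statistics are left NA; see :func:`summarize_region`.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    dm_flags = np.asarray(dm_flags, dtype=bool)
    testable = np.asarray(testable, dtype=bool)
    regions: list[DMRegion] = []
    dm_idx = np.flatnonzero(dm_flags)
    if len(dm_idx) == 0:
        return regions
    run_start = dm_idx[0]
    prev = dm_idx[0]
    for i in dm_idx[1:]:
        if chroms[i] != chroms[prev] or positions[i] - positions[prev] > max_gap:
            regions.append(_close_run(chroms, positions, dm_flags, testable,
                                      run_start, prev))
            run_start = i
        prev = i
    regions.append(_close_run(chroms, positions, dm_flags, testable,
                              run_start, prev))
    return regions


def _close_run(chroms, positions, dm_flags, testable, first: int, last: int
               ) -> DMRegion:
    inside = slice(first, last + 1)
    n_cpgs = int(testable[inside].sum())
    n_sig = int(dm_flags[inside].sum())
    return DMRegion(
        chrom=str(chroms[first]),
        start=int(positions[first]) - 1,
        end=int(positions[last]),
        n_cpgs=n_cpgs,
        n_sig=n_sig,
        first_site=int(first),
        last_site=int(last),
    )


def _pooled_level(meths: np.ndarray, totals: np.ndarray) -> float:
    tot = totals.sum()
    return float(meths.sum() / tot) if tot > 0 else float("nan")


def summarize_region(region: DMRegion, counts: CountTable,
                     design: DesignMatrix, test_factor: str,
                     testable: Sequence[bool] | None = None) -> DMRegion:
    """Fill in ``log_odds`` and ``min_meth_diff`` for one region.

    Group A is test factor = 0, group B is test factor = 1, matching the
    per-site result convention. If either group has zero coverage over
    the whole region the summaries stay NA.
    """
    j = design.factor_columns(test_factor)[0]
    in_b = design.X[:, j] == 1
    rows = slice(region.first_site, region.last_site + 1)
    tot = counts.totals[rows]
    met = counts.meths[rows]
    if testable is not None:
        keep = np.asarray(testable, dtype=bool)[rows]
        tot, met = tot[keep], met[keep]

    tot_a, met_a = tot[:, ~in_b], met[:, ~in_b]
    tot_b, met_b = tot[:, in_b], met[:, in_b]
    pooled_ta, pooled_tb = tot_a.sum(), tot_b.sum()
    if pooled_ta == 0 or pooled_tb == 0:
        return region
    ma, mb = met_a.sum(), met_b.sum()
    odds_a = (ma + 0.5) / (pooled_ta - ma + 0.5)
    odds_b = (mb + 0.5) / (pooled_tb - mb + 0.5)
    region.log_odds = float(math.log(odds_a / odds_b))

    site_ta = tot_a.sum(axis=1)
    site_tb = tot_b.sum(axis=1)
    both = (site_ta > 0) & (site_tb > 0)
    if both.any():
        lev_a = met_a.sum(axis=1)[both] / site_ta[both]
        lev_b = met_b.sum(axis=1)[both] / site_tb[both]
        region.min_meth_diff = float(np.abs(lev_a - lev_b).min())
    return region


def filter_regions(regions: Sequence[DMRegion], min_cpgs: int = 10,
                   min_diff: float = 0.0) -> list[DMRegion]:
    """Keep regions with at least ``min_cpgs`` tested CpGs and minimum
    methylation difference strictly above ``min_diff`` (NA never passes)."""
    if min_cpgs < 0 or min_diff < 0:
        raise ValueError("thresholds must be nonnegative")
    return [
        r for r in regions
        if r.n_cpgs >= min_cpgs
        and not math.isnan(r.min_meth_diff)
        and r.min_meth_diff > min_diff
    ]
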