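"""Synthetic WGBS benchmark generator and Jaccard evaluation.

The generator emulates a two-group bisulfite experiment: CpG sites are
laid out along one chromosome with inter-site gaps uniform on
[2, max_gap_bp]; a set of non-overlapping DM regions of 10-100 CpGs is
placed at random site runs. At every site and sample a methylation level
p is drawn — Beta(2,2) at non-DM sites (alternatives: Beta(1.5,1.5), or
the dispersion-free constant 0.7), Beta(6,1.5) in case samples and
Beta(1.5,6) in control samples at DM sites — coverage n comes from a
Poisson model, and the methylated read count is Binomial(n, p). Drawing
the level independently per replicate is what makes the counts
beta-binomial across samples (dispersion 1/(a+b+1): 0.2 for the Beta(2,2)
null, about 0.118 at DM sites).

A single master seed drives independent substreams for layout, levels,
coverage and counts, so the layout can be held fixed while counts vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from . import combine, regions as regions_mod
from .betabinom import test_site
from .tables import CountTable, DesignMatrix, SiteKey


@dataclass(frozen=True)
class LevelDist:
    """Methylation-level distribution: Beta(a, b) or a constant level."""

    kind: str                    # "beta" or "constant"
    a: float = 0.0
    b: float = 0.0
    value: float = 0.0

    @staticmethod
    def beta(a: float, b: float) -> "LevelDist":
        if a <= 0 or b <= 0:
            raise ValueError("beta shape parameters must be positive")
        return LevelDist(kind="beta", a=a, b=b)

    @staticmethod
    def constant(value: float) -> "LevelDist":
        if not 0.0 <= value <= 1.0:
            raise ValueError("constant level must lie in [0, 1]")
        return LevelDist(kind="constant", value=value)

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size=size)
        return np.full(size, self.value)

    def mean(self) -> float:
        return self.a / (self.a + self.b) if self.kind == "beta" else self.value

    def variance(self) -> float:
        if self.kind == "constant":
            return 0.0
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))


@dataclass
class SimConfig:
    """Benchmark configuration; defaults mirror the 6+6 reference design."""

    n_case: int = 6
    n_control: int = 6
    n_sites: int = 20_000
    n_regions: int = 200
    region_size_range: tuple[int, int] = (10, 100)
    max_gap_bp: int = 200
    coverage_lambda: float = 10.0
    min_coverage: int = 0
    coverage_file: str | None = None        # empirical per-read-depth hook
    null_levels: LevelDist = field(default_factory=lambda: LevelDist.beta(2, 2))
    dm_case_levels: LevelDist = field(default_factory=lambda: LevelDist.beta(6, 1.5))
    dm_control_levels: LevelDist = field(default_factory=lambda: LevelDist.beta(1.5, 6))
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.region_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid region size range")
        if min(self.n_case, self.n_control, self.n_sites) < 1 or self.n_regions < 0:
            raise ValueError("sample, site and region counts must be positive")
        if self.n_regions * hi > self.n_sites:
            raise ValueError(
                "infeasible layout: n_regions * max region size exceeds n_sites"
            )


@dataclass
class TruthSet:
    """Ground truth of a simulated dataset."""

    dm_site_keys: set[SiteKey]
    region_intervals: list[tuple[str, int, int]]   # 0-based half-open spans
    dm_mask: np.ndarray                            # site-order boolean


def _empirical_coverage(path: str, rng: np.random.Generator, size) -> np.ndarray:
    depths = np.loadtxt(path, dtype=np.int64, ndmin=1)
    if len(depths) == 0 or (depths < 0).any():
        raise ValueError("empirical coverage file must list nonnegative depths")
    return rng.choice(depths, size=size, replace=True)


def _place_regions(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Boolean DM mask over site indices: non-overlapping random runs."""
    mask = np.zeros(cfg.n_sites, dtype=bool)
    if cfg.n_regions == 0:
        return mask
    lo, hi = cfg.region_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_regions)
    free = cfg.n_sites - int(sizes.sum())
    n_gaps = cfg.n_regions + 1
    if free < n_gaps:
        raise ValueError("infeasible layout: not enough non-DM sites between regions")
    # random composition of the free sites into gaps, each gap >= 1
    extra = rng.multinomial(free - n_gaps, np.full(n_gaps, 1.0 / n_gaps))
    gaps = extra + 1
    cursor = 0
    for g, size in zip(gaps[:-1], sizes):
        cursor += int(g)
        mask[cursor:cursor + int(size)] = True
        cursor += int(size)
    return mask


def simulate_dataset(cfg: SimConfig) -> tuple[CountTable, DesignMatrix, TruthSet]:
    """Draw one dataset; bit-for-bit reproducible from ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_layout, rng_levels, rng_cov, rng_counts = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    s = cfg.n_control + cfg.n_case

    gaps = rng_layout.integers(2, cfg.max_gap_bp + 1, size=cfg.n_sites)
    positions = np.cumsum(gaps)
    dm_mask = _place_regions(rng_layout, cfg)

    is_case = np.zeros(s, dtype=bool)
    is_case[cfg.n_control:] = True
    levels = cfg.null_levels.draw(rng_levels, (cfg.n_sites, s))
    n_dm = int(dm_mask.sum())
    if n_dm:
        levels[np.ix_(dm_mask, ~is_case)] = cfg.dm_control_levels.draw(
            rng_levels, (n_dm, cfg.n_control)
        )
        levels[np.ix_(dm_mask, is_case)] = cfg.dm_case_levels.draw(
            rng_levels, (n_dm, cfg.n_case)
        )

    if cfg.coverage_file is not None:
        totals = _empirical_coverage(cfg.coverage_file, rng_cov, (cfg.n_sites, s))
    else:
        totals = rng_cov.poisson(cfg.coverage_lambda, size=(cfg.n_sites, s))
    if cfg.min_coverage > 0:
        totals = np.maximum(totals, cfg.min_coverage)
    meths = rng_counts.binomial(totals, levels)

    sites = [SiteKey(chrom=cfg.chrom, pos=int(p)) for p in positions]
    samples = [f"control_{i + 1}" for i in range(cfg.n_control)] + [
        f"case_{i + 1}" for i in range(cfg.n_case)
    ]
    table = CountTable(sites=sites, samples=samples, totals=totals, meths=meths)
    design = DesignMatrix(
        samples=samples,
        factors=["base", "case"],
        X=np.column_stack([np.ones(s, dtype=np.int64), is_case.astype(np.int64)]),
    )

    intervals: list[tuple[str, int, int]] = []
    idx = np.flatnonzero(dm_mask)
    if len(idx):
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(idx) - 1]])
        for a, b in zip(starts, ends):
            intervals.append(
                (cfg.chrom, int(positions[idx[a]]) - 1, int(positions[idx[b]]))
            )
    truth = TruthSet(
        dm_site_keys={sites[i] for i in idx},
        region_intervals=intervals,
        dm_mask=dm_mask,
    )
    return table, design, truth


def jaccard(called: set, truth: set) -> float:
    """|M intersect T| / |M union T|; 1.0 when both sets are empty."""
    union = called | truth
    if not union:
        return 1.0
    return len(called & truth) / len(union)


@dataclass
class BenchmarkResult:
    jaccard: float
    tp: int
    fp: int
    fn: int
    n_called: int
    n_true: int


def run_benchmark(cfg: SimConfig, *, test_factor: str = "case",
                  window_bp: int = 200, max_dist: int = 200,
                  fdr_cutoff: float = 0.01) -> BenchmarkResult:
    """simulate -> regression -> combine -> FDR -> call, scored against
    the generator's truth set."""
    table, design, truth = simulate_dataset(cfg)
    p_raw = np.array([
        test_site(design, test_factor, table.totals[r], table.meths[r]).p_raw
        for r in range(table.n_sites)
    ])
    p_comb = combine.adjust_all(
        table.chroms(), table.positions(), p_raw,
        window_bp=window_bp, max_dist=max_dist,
    )
    p_adj = combine.bh_fdr(p_comb)
    dm = regions_mod.call_dm_sites(p_adj, cutoff=fdr_cutoff)
    called = {table.sites[i] for i in np.flatnonzero(dm)}
    tp = len(called & truth.dm_site_keys)
    fp = len(called - truth.dm_site_keys)
    fn = len(truth.dm_site_keys - called)
    return BenchmarkResult(
        jaccard=jaccard(called, truth.dm_site_keys),
        tp=tp, fp=fp, fn=fn,
        n_called=len(called), n_true=len(truth.dm_site_keys),
    )
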