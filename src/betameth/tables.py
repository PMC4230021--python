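"""Core tabular containers: site keys, count tables, and design matrices.

A methylation count table holds, for every cytosine site and every sample,
the pair (total reads covering the site, reads indicating methylation).
The design matrix encodes sample-level binary experimental factors; its
first column is conventionally the intercept ("base").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class SiteKey:
    """Genomic identity of a single cytosine site.

    ``pos`` is 1-based. Ordering is lexicographic on
    (chrom, pos, strand, context), which is the table sort order.
    """

    chrom: str
    pos: int
    strand: str = "+"
    context: str = "CpG"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site position must be >= 1, got {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}:{self.context}"


@dataclass
class CountTable:
    """Sites x samples matrix of (total, methylated) read counts.

    ``totals[r, c]`` is the coverage of site ``r`` in sample ``c`` and
    ``meths[r, c]`` the number of those reads indicating methylation.
    Rows are sorted by (chrom, pos); zero coverage is a legal value and
    means the site is unobserved in that sample.
    """

    sites: list[SiteKey]
    samples: list[str]
    totals: np.ndarray
    meths: np.ndarray

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=np.int64)
        self.meths = np.asarray(self.meths, dtype=np.int64)
        r, s = len(self.sites), len(self.samples)
        if self.totals.shape != (r, s) or self.meths.shape != (r, s):
            raise ValueError(
                f"count matrices must be {r}x{s}; got totals {self.totals.shape}, "
                f"meths {self.meths.shape}"
            )
        if len(set(self.samples)) != s:
            raise ValueError("duplicate sample names")
        if (self.totals < 0).any() or (self.meths < 0).any():
            raise ValueError("negative read counts")
        if (self.meths > self.totals).any():
            r_bad, c_bad = np.argwhere(self.meths > self.totals)[0]
            raise ValueError(
                f"methylated count exceeds total at site {self.sites[r_bad]} "
                f"sample {self.samples[c_bad]}"
            )
        keys = [(k.chrom, k.pos) for k in self.sites]
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("sites must be sorted by (chrom, pos)")
        if len(set(self.sites)) != r:
            raise ValueError("duplicate site keys")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chroms(self) -> np.ndarray:
        return np.array([k.chrom for k in self.sites])

    def positions(self) -> np.ndarray:
        return np.array([k.pos for k in self.sites], dtype=np.int64)


@dataclass
class DesignMatrix:
    """Samples x factors binary model matrix with named columns.

    The first column is expected to be the all-ones intercept named
    "base"; it is never added implicitly, so the full/reduced model pair
    of a likelihood-ratio test is always explicit.
    """

    samples: list[str]
    factors: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        s, t = len(self.samples), len(self.factors)
        if self.X.shape != (s, t):
            raise ValueError(f"design matrix must be {s}x{t}, got {self.X.shape}")
        if len(set(self.factors)) != t:
            raise ValueError("duplicate factor names")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("non-binary design entry")
        if np.linalg.matrix_rank(self.X.astype(float)) < t:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def factor_columns(self, test_factor: str | Sequence[str]) -> list[int]:
        """Column indices for a factor name (or several, for multi-level
        factors encoded as several binary columns)."""
        names = [test_factor] if isinstance(test_factor, str) else list(test_factor)
        cols = []
        for name in names:
            if name not in self.factors:
                raise ValueError(f"unknown test factor {name!r}")
            cols.append(self.factors.index(name))
        return cols

    def drop(self, test_factor: str | Sequence[str]) -> "DesignMatrix":
        """Reduced design with the test-factor column(s) removed."""
        cols = set(self.factor_columns(test_factor))
        if len(cols) == self.n_factors:
            raise ValueError("reduced design would have no columns")
        keep = [j for j in range(self.n_factors) if j not in cols]
        return DesignMatrix(
            samples=list(self.samples),
            factors=[self.factors[j] for j in keep],
            X=self.X[:, keep].copy(),
        )

    def check_samples(self, table: CountTable) -> None:
        if list(self.samples) != list(table.samples):
            raise ValueError(
                "design matrix samples do not match count table samples "
                f"({self.samples} vs {table.samples})"
            )


@dataclass
class SiteResult:
    """Per-site outcome of the differential-methylation workflow.

    ``nan`` encodes NA throughout (untestable site, or a stage not yet
    run). ``meth_a``/``meth_b`` are coverage-pooled methylation levels of
    the two test-factor groups (A: factor = 0, B: factor = 1).
    """

    key: SiteKey
    p_raw: float = float("nan")
    p_combined: float = float("nan")
    p_adjusted: float = float("nan")
    meth_a: float = float("nan")
    meth_b: float = float("nan")
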