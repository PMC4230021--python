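"""Correlation-adjusted p-value combination (weighted-Z / Stouffer-Liptak).

Raw per-site p-values are transformed to Z-scores z_i = Phi^{-1}(1 - p_i)
and, for each testable site, combined with its testable neighbors inside a
symmetric genomic window:

    p_combined = 1 - Phi( sum_i z_i / sqrt(n + 2 * sum_{i<j} rho_ij) ),

where rho_ij is the correlation of Z-scores at the genomic distance
|pos_i - pos_j|, estimated genome-wide per integer distance bin. Under
independence the denominator reduces to sqrt(n), the classic Stouffer
combination. Combined p-values are then Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_CLIP_EPS = 1e-15
MIN_PAIRS_PER_BIN = 50
_RHO_CLIP = 0.999


@dataclass
class ZSeries:
    """Per-site Z-scores with genomic coordinates.

    ``z`` is nan exactly where ``testable`` is False.
    """

    chroms: np.ndarray
    positions: np.ndarray
    z: np.ndarray
    testable: np.ndarray


@dataclass
class CorrelationProfile:
    """Estimated Z-score correlation per integer genomic distance.

    ``rho[d]`` for d = 0..max_dist; distances beyond ``max_dist`` are
    treated as uncorrelated. Bins with fewer than ``min_pairs`` pairs
    inherit the nearest populated bin's value, defaulting to 0 when no
    bin is populated.
    """

    max_dist: int
    rho: np.ndarray

    def lookup(self, dist: int) -> float:
        if dist > self.max_dist:
            return 0.0
        return float(self.rho[dist])


def z_transform(p_values, clip_eps: float = DEFAULT_CLIP_EPS) -> np.ndarray:
    """z_i = Phi^{-1}(1 - p_i), with p clipped away from {0, 1}; NA
    propagates."""
    if not 0.0 < clip_eps < 0.5:
        raise ValueError("clip_eps must lie in (0, 0.5)")
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0.0) | (p[ok] > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    z = np.full(p.shape, np.nan)
    z[ok] = stats.norm.isf(np.clip(p[ok], clip_eps, 1.0 - clip_eps))
    return z


def make_zseries(chroms, positions, p_values,
                 clip_eps: float = DEFAULT_CLIP_EPS) -> ZSeries:
    p = np.asarray(p_values, dtype=float)
    return ZSeries(
        chroms=np.asarray(chroms),
        positions=np.asarray(positions, dtype=np.int64),
        z=z_transform(p, clip_eps),
        testable=~np.isnan(p),
    )


def estimate_correlation(zs: ZSeries, max_dist: int = 200,
                         min_pairs: int = MIN_PAIRS_PER_BIN) -> CorrelationProfile:
    """Pearson correlation of Z-scores per genomic distance bin.

    Pools, genome-wide, every ordered pair of testable sites on the same
    chromosome at exact distance d, for d = 1..max_dist.
    """
    if int(zs.testable.sum()) < 2:
        raise ValueError("need at least 2 testable sites to estimate correlation")
    nbins = max_dist + 1
    cnt = np.zeros(nbins)
    sx = np.zeros(nbins)
    sy = np.zeros(nbins)
    sxx = np.zeros(nbins)
    syy = np.zeros(nbins)
    sxy = np.zeros(nbins)
    for chrom in np.unique(zs.chroms):
        sel = (zs.chroms == chrom) & zs.testable
        pos = zs.positions[sel]
        z = zs.z[sel]
        order = np.argsort(pos, kind="stable")
        pos, z = pos[order], z[order]
        n = len(pos)
        k = 1
        while k < n:
            d = pos[k:] - pos[:-k]
            mask = d <= max_dist
            if not mask.any():
                break
            dm = d[mask]
            x = z[:-k][mask]
            y = z[k:][mask]
            cnt += np.bincount(dm, minlength=nbins)[:nbins]
            sx += np.bincount(dm, weights=x, minlength=nbins)[:nbins]
            sy += np.bincount(dm, weights=y, minlength=nbins)[:nbins]
            sxx += np.bincount(dm, weights=x * x, minlength=nbins)[:nbins]
            syy += np.bincount(dm, weights=y * y, minlength=nbins)[:nbins]
            sxy += np.bincount(dm, weights=x * y, minlength=nbins)[:nbins]
            k += 1
    rho = np.full(nbins, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = sx / cnt
        my = sy / cnt
        vx = sxx / cnt - mx**2
        vy = syy / cnt - my**2
        cov = sxy / cnt - mx * my
        good = (cnt >= min_pairs) & (vx > 0) & (vy > 0)
        rho[good] = cov[good] / np.sqrt(vx[good] * vy[good])
    rho = np.clip(rho, -_RHO_CLIP, _RHO_CLIP)
    # sparse bins inherit the nearest populated bin; all-empty -> 0
    pop = np.flatnonzero(~np.isnan(rho))
    if len(pop) == 0:
        rho = np.zeros(nbins)
    else:
        for d in np.flatnonzero(np.isnan(rho)):
            nearest = pop[np.argmin(np.abs(pop - d))]
            rho[d] = rho[nearest]
    return CorrelationProfile(max_dist=max_dist, rho=rho)


def _window_combine(pos: np.ndarray, z: np.ndarray, profile: CorrelationProfile,
                    lo: int, hi: int, center_in_window: bool = True) -> float:
    """Weighted-Z combination of z[lo:hi] (testable sites only)."""
    zw = z[lo:hi]
    pw = pos[lo:hi]
    n = len(zw)
    s = float(zw.sum())
    var = float(n)
    for i in range(n - 1):
        d = pw[i + 1:] - pw[i]
        var += 2.0 * sum(profile.lookup(int(dd)) for dd in d)
    var = max(var, 0.1 * n)
    return float(stats.norm.sf(s / np.sqrt(var)))


def combine_site(zs: ZSeries, profile: CorrelationProfile, center: int,
                 window_bp: int = 200) -> float:
    """Combined p-value for one site over its +-window_bp/2 neighborhood.

    The window holds every testable same-chromosome site within
    window_bp/2 of the center (center included); a singleton window
    returns the raw p unchanged. An untestable center returns nan.
    """
    if not zs.testable[center]:
        return float("nan")
    half = window_bp / 2.0
    chrom = zs.chroms[center]
    cpos = zs.positions[center]
    sel = (zs.chroms == chrom) & zs.testable & (np.abs(zs.positions - cpos) <= half)
    pos = zs.positions[sel]
    z = zs.z[sel]
    order = np.argsort(pos, kind="stable")
    return _window_combine(pos[order], z[order], profile, 0, int(sel.sum()))


def adjust_all(chroms, positions, p_values, window_bp: int = 200,
               max_dist: int = 200, clip_eps: float = DEFAULT_CLIP_EPS,
               min_pairs: int = MIN_PAIRS_PER_BIN) -> np.ndarray:
    """Combined p-value for every testable site, one genome-wide pass.

    Estimates the correlation profile once, then slides the window over
    each chromosome; chromosome boundaries are respected. Returns nan at
    untestable sites.
    """
    zs = make_zseries(chroms, positions, p_values, clip_eps)
    out = np.full(len(zs.z), np.nan)
    if int(zs.testable.sum()) == 0:
        return out
    if int(zs.testable.sum()) == 1:
        out[zs.testable] = np.asarray(p_values, dtype=float)[zs.testable]
        return out
    profile = estimate_correlation(zs, max_dist=max_dist, min_pairs=min_pairs)
    half = window_bp / 2.0
    idx_all = np.arange(len(zs.z))
    for chrom in np.unique(zs.chroms):
        sel = (zs.chroms == chrom) & zs.testable
        idx = idx_all[sel]
        pos = zs.positions[sel]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        z = zs.z[sel][order]
        n = len(pos)
        lo = 0
        hi = 0
        for c in range(n):
            while pos[c] - pos[lo] > half:
                lo += 1
            if hi < c + 1:
                hi = c + 1
            while hi < n and pos[hi] - pos[c] <= half:
                hi += 1
            out[idx[c]] = _window_combine(pos, z, profile, lo, hi)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NAs are excluded from the
    ranking and returned as NA."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
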