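"""Beta-binomial probability machinery, per-site regression, and the LRT.

Model
-----
At one site observed in samples i = 1..s with read pairs (m_i, n_i),

    M_i ~ BetaBinomial(n_i, pi_i, gamma),   logit(pi_i) = x_i' eta,

where pi is the mean methylation level, gamma in [0, 1) the dispersion
(gamma = 0 recovers the binomial), and gamma is shared across samples at
the site. In shape parameters, alpha = pi*(1/gamma - 1) and
beta = (1-pi)*(1/gamma - 1). Parameters (eta, gamma) are estimated by
maximum likelihood; differential methylation with respect to one factor
is assessed by the likelihood-ratio test of the full model against the
reduced model with that factor's column(s) removed, with a chi-square
reference distribution (df = number of dropped columns).

Samples with zero coverage at the site carry no information and are
excluded from the likelihood. A site is *untestable* (p = NA) when,
after dropping them, the design loses full column rank or one level of
the test factor retains no coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .tables import DesignMatrix

GAMMA_MIN = 1e-6
GAMMA_MAX = 1.0 - 1e-6
_ETA_BOUND = 30.0
_PI_EPS = 1e-12
# logit-scale bounds for the dispersion during optimization
_THETA_LO = float(special.logit(GAMMA_MIN))
_THETA_HI = float(special.logit(GAMMA_MAX))


@dataclass
class SiteFit:
    """One fitted beta-binomial regression at a single site."""

    eta: np.ndarray          # regression coefficients, log-odds scale
    gamma: float             # common dispersion
    loglik: float
    converged: bool
    n_used: int              # samples with nonzero coverage


@dataclass
class SiteTest:
    """Full-vs-reduced likelihood-ratio test at a single site."""

    full: SiteFit | None
    reduced: SiteFit | None
    df: int
    p_raw: float             # nan marks an untestable site


def _check_domain(m, n, pi, gamma) -> None:
    m = np.asarray(m)
    n = np.asarray(n)
    if np.any(m < 0) or np.any(m > n):
        raise ValueError("require 0 <= m <= n")
    pi = np.asarray(pi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        raise ValueError("require 0 < pi < 1")
    if np.any(gamma < 0.0) or np.any(gamma >= 1.0):
        raise ValueError("require 0 <= gamma < 1")


def log_pmf(m, n, pi, gamma):
    """Log probability mass of BetaBinomial(n, pi, gamma) at m.

    Evaluated through log-gamma functions for stability; gamma = 0 is the
    binomial special case and is returned exactly. Inputs broadcast.
    """
    _check_domain(m, n, pi, gamma)
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    pi = np.asarray(pi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    out = np.empty(np.broadcast(m, n, pi, gamma).shape, dtype=float)
    m, n, pi, gamma = np.broadcast_arrays(m, n, pi, gamma)
    # below ~1e-12 the shape parameters overflow double precision and the
    # distribution is numerically binomial anyway
    binom_mask = gamma < 1e-12
    if binom_mask.any():
        out[binom_mask] = stats.binom.logpmf(
            m[binom_mask], n[binom_mask], pi[binom_mask]
        )
    # tiny positive gamma: betaln cancels catastrophically at huge shapes,
    # so use the exact rising-factorial sum for integer counts
    small = (~binom_mask) & (gamma < 1e-4)
    if small.any():
        idx = np.flatnonzero(small.ravel())
        flat = out.ravel()
        for i in idx:
            mi, ni = m.ravel()[i], n.ravel()[i]
            ci = 1.0 / gamma.ravel()[i] - 1.0
            ai = pi.ravel()[i] * ci
            bi = (1.0 - pi.ravel()[i]) * ci
            lchoose = (special.gammaln(ni + 1) - special.gammaln(mi + 1)
                       - special.gammaln(ni - mi + 1))
            flat[i] = (
                lchoose
                + np.log(ai + np.arange(mi)).sum()
                + np.log(bi + np.arange(ni - mi)).sum()
                - np.log(ci + np.arange(ni)).sum()
            )
    bb = ~binom_mask & ~small
    if bb.any():
        c = 1.0 / gamma[bb] - 1.0
        a = pi[bb] * c
        b = (1.0 - pi[bb]) * c
        mm, nn = m[bb], n[bb]
        out[bb] = (
            special.gammaln(nn + 1)
            - special.gammaln(mm + 1)
            - special.gammaln(nn - mm + 1)
            + special.betaln(mm + a, nn - mm + b)
            - special.betaln(a, b)
        )
    return out if out.ndim else float(out)


def moments(n, pi, gamma):
    """Mean and variance of BetaBinomial(n, pi, gamma):
    E(M) = n*pi, Var(M) = n*pi*(1-pi)*(1 + (n-1)*gamma)."""
    _check_domain(0, n, pi, gamma)
    n = np.asarray(n, dtype=float)
    mean = n * pi
    var = n * pi * (1.0 - pi) * (1.0 + (n - 1.0) * gamma)
    if mean.ndim == 0:
        return float(mean), float(var)
    return mean, var


def loglik_regression(eta, gamma, X, totals, meths):
    """Log-likelihood of the regression at one site.

    Samples with zero coverage are excluded from the sum; an all-zero
    coverage vector raises.
    """
    totals = np.asarray(totals)
    meths = np.asarray(meths)
    keep = totals > 0
    if not keep.any():
        raise ValueError("site has no covered samples")
    X = np.asarray(X, dtype=float).reshape(len(totals), -1)
    pi = special.expit(X[keep] @ np.asarray(eta, dtype=float))
    pi = np.clip(pi, _PI_EPS, 1.0 - _PI_EPS)
    return float(np.sum(log_pmf(meths[keep], totals[keep], pi, gamma)))


def _neg_loglik_and_grad(params, X, m, n):
    """Negative log-likelihood and gradient over (eta, theta=logit gamma).

    With c = 1/gamma - 1 = exp(-theta), a_i = pi_i c, b_i = (1-pi_i) c:
      d/d eta_j = sum_i c pi_i(1-pi_i) X_ij [psi(m+a)-psi(a)-psi(n-m+b)+psi(b)]
      d/d c     = sum_i [pi(psi(m+a)-psi(a)) + (1-pi)(psi(n-m+b)-psi(b))
                         + psi(c) - psi(n+c)]
      d/d theta = -c * d/dc.
    """
    eta = params[:-1]
    theta = params[-1]
    c = np.exp(-theta)
    pi = special.expit(X @ eta)
    pi = np.clip(pi, _PI_EPS, 1.0 - _PI_EPS)
    a = pi * c
    b = (1.0 - pi) * c
    ll = np.sum(
        special.betaln(m + a, n - m + b)
        - special.betaln(a, b)
        + special.gammaln(n + 1)
        - special.gammaln(m + 1)
        - special.gammaln(n - m + 1)
    )
    da = special.psi(m + a) - special.psi(a)
    db = special.psi(n - m + b) - special.psi(b)
    w = c * pi * (1.0 - pi) * (da - db)
    g_eta = X.T @ w
    g_c = np.sum(pi * da + (1.0 - pi) * db) + len(m) * special.psi(c) - np.sum(
        special.psi(n + c)
    )
    g_theta = -c * g_c
    grad = np.concatenate([g_eta, [g_theta]])
    return -ll, -grad


def _start_eta(X, m, n):
    """Deterministic start: least squares on smoothed per-sample logits,
    falling back to zeros on any numerical failure."""
    with np.errstate(all="ignore"):
        zeta = special.logit((m + 0.5) / (n + 1.0))
        try:
            eta0, *_ = np.linalg.lstsq(X, zeta, rcond=None)
        except np.linalg.LinAlgError:
            return np.zeros(X.shape[1])
    if not np.all(np.isfinite(eta0)):
        return np.zeros(X.shape[1])
    return np.clip(eta0, -_ETA_BOUND + 1, _ETA_BOUND - 1)


def fit_site(X, totals, meths, *, gamma_start: float = 0.05,
             max_iter: int = 500) -> SiteFit | None:
    """Maximum-likelihood fit of (eta, gamma) at one site.

    Returns ``None`` (the untestable-site signal) when fewer covered
    samples than parameters remain or the covered-sample design loses
    full column rank. Optimizes over (eta, logit gamma) with L-BFGS-B
    from a deterministic start, retrying with Nelder-Mead on failure.
    """
    totals = np.asarray(totals, dtype=np.int64)
    meths = np.asarray(meths, dtype=np.int64)
    X = np.asarray(X, dtype=float).reshape(len(totals), -1)
    t = X.shape[1]
    keep = totals > 0
    k = int(keep.sum())
    if k < t:
        return None
    Xk = X[keep]
    if np.linalg.matrix_rank(Xk) < t:
        return None
    m = meths[keep].astype(float)
    n = totals[keep].astype(float)

    x0 = np.concatenate([_start_eta(Xk, m, n), [special.logit(gamma_start)]])
    bounds = [(-_ETA_BOUND, _ETA_BOUND)] * t + [(_THETA_LO, _THETA_HI)]
    opts = {"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-6}
    res = optimize.minimize(
        _neg_loglik_and_grad, x0, args=(Xk, m, n), jac=True,
        method="L-BFGS-B", bounds=bounds, options=opts,
    )
    converged = bool(res.success)
    if not converged:
        # a line-search "ABNORMAL" stop at the optimum is common with a
        # tight ftol; a restart that cannot move and leaves only a tiny
        # gradient counts as converged (relative change < 1e-8)
        f_prev = float(res.fun)
        res2 = optimize.minimize(
            _neg_loglik_and_grad, res.x, args=(Xk, m, n), jac=True,
            method="L-BFGS-B", bounds=bounds, options=opts,
        )
        if res2.fun <= res.fun:
            res = res2
        converged = bool(res2.success) or (
            abs(float(res2.fun) - f_prev) <= 1e-8 * max(1.0, abs(f_prev))
            and np.max(np.abs(res2.jac)) < 1e-2
        )
    if not converged:
        res3 = optimize.minimize(
            lambda p, *a: _neg_loglik_and_grad(p, *a)[0], res.x,
            args=(Xk, m, n), method="Nelder-Mead", bounds=bounds,
            options={"maxiter": 4 * max_iter, "fatol": 1e-10, "xatol": 1e-8},
        )
        if res3.fun <= res.fun:
            res = res3
            converged = bool(res3.success)
    return SiteFit(
        eta=res.x[:-1].copy(),
        gamma=float(special.expit(res.x[-1])),
        loglik=-float(res.fun),
        converged=converged,
        n_used=k,
    )


def _group_has_no_coverage(col: np.ndarray, totals: np.ndarray) -> bool:
    for level in (0, 1):
        sel = col == level
        if sel.any() and totals[sel].sum() == 0:
            return True
    return False


def test_site(design: DesignMatrix, test_factor: str | Sequence[str],
              totals, meths) -> SiteTest:
    """Likelihood-ratio test of the test factor at one site.

    ``p_raw`` is the upper chi-square tail of 2*(loglik_full -
    loglik_reduced) with df = number of dropped columns; tiny negative
    statistics from finite-precision optimization are clamped to zero.
    Untestable sites get ``p_raw = nan``.
    """
    totals = np.asarray(totals, dtype=np.int64)
    meths = np.asarray(meths, dtype=np.int64)
    cols = design.factor_columns(test_factor)
    if 0 in cols and "base" in design.factors and design.factors[0] == "base":
        raise ValueError("cannot test the intercept column")
    reduced_design = design.drop(test_factor)
    df = len(cols)

    untestable = any(
        _group_has_no_coverage(design.X[:, j], totals) for j in cols
    )
    full = None if untestable else fit_site(design.X, totals, meths)
    if full is None:
        return SiteTest(full=None, reduced=None, df=df, p_raw=float("nan"))
    reduced = fit_site(reduced_design.X, totals, meths)
    if reduced is None:
        return SiteTest(full=full, reduced=None, df=df, p_raw=float("nan"))

    # nesting guard: restart the full fit from the reduced optimum if the
    # optimizer left it below the reduced log-likelihood
    if full.loglik < reduced.loglik - 1e-9:
        keep_cols = [j for j in range(design.n_factors) if j not in cols]
        eta0 = np.zeros(design.n_factors)
        eta0[keep_cols] = reduced.eta
        refit = _refit_from(design.X, totals, meths, eta0, reduced.gamma)
        if refit is not None and refit.loglik > full.loglik:
            full = refit

    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(stat, df))
    return SiteTest(full=full, reduced=reduced, df=df, p_raw=p)


def _refit_from(X, totals, meths, eta0, gamma0) -> SiteFit | None:
    totals = np.asarray(totals, dtype=np.int64)
    keep = totals > 0
    Xk = np.asarray(X, dtype=float)[keep]
    m = np.asarray(meths, dtype=float)[keep]
    n = totals[keep].astype(float)
    t = Xk.shape[1]
    theta0 = float(special.logit(np.clip(gamma0, GAMMA_MIN, GAMMA_MAX)))
    x0 = np.concatenate([np.clip(eta0, -_ETA_BOUND + 1, _ETA_BOUND - 1), [theta0]])
    bounds = [(-_ETA_BOUND, _ETA_BOUND)] * t + [(_THETA_LO, _THETA_HI)]
    res = optimize.minimize(
        _neg_loglik_and_grad, x0, args=(Xk, m, n), jac=True,
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-6},
    )
    return SiteFit(
        eta=res.x[:-1].copy(), gamma=float(special.expit(res.x[-1])),
        loglik=-float(res.fun), converged=bool(res.success),
        n_used=int(keep.sum()),
    )
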