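"""Maximum-likelihood polychoric correlation and the multiple-threshold fit test.

Two ordinal co-twin statuses are modelled as discretisations of a
standard bivariate normal liability with correlation rho; the polychoric
correlation is the ML estimate of rho, maximising the multinomial
likelihood jointly over rho and the category cutpoints (the tetrachoric
correlation is the 2x2 special case).  The multiple-threshold model —
ordered categories as severity levels on a single liability dimension —
is testable by a chi-square goodness-of-fit statistic comparing observed
cell counts to those implied by the fitted bivariate-normal model.

Estimation is one-stage joint ML on transformed scales (Fisher z for
rho, first threshold plus log-spacings for the cutpoints) so the
constraints |rho| < 1 and threshold monotonicity are implicit.  The rho
confidence interval is profile-likelihood based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from ._bvn import bvn_cdf, bvn_rect
from .familial_clustering import PairTable

__all__ = [
    "BvnSpec",
    "PolychoricResult",
    "bvn_rect",
    "bvn_cell_probs",
    "fit_polychoric",
    "multiple_threshold_gof",
]

_TINY = 1e-300


@dataclass(frozen=True)
class BvnSpec:
    """A discretised bivariate normal: correlation plus per-margin cutpoints."""

    rho: float
    row_thresholds: tuple[float, ...]
    col_thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        for t in (self.row_thresholds, self.col_thresholds):
            if np.any(np.diff(t) <= 0):
                raise ValueError("thresholds must be strictly increasing")


def bvn_cell_probs(rho: float, row_thresholds, col_thresholds) -> np.ndarray:
    """Cell probabilities of the discretised bivariate normal.

    Returns a (len(row_thresholds)+1) x (len(col_thresholds)+1) matrix of
    rectangle probabilities; rows/columns are the ordinal categories.
    """
    rt = np.concatenate(([-np.inf], np.asarray(row_thresholds, float), [np.inf]))
    ct = np.concatenate(([-np.inf], np.asarray(col_thresholds, float), [np.inf]))
    grid = bvn_cdf(rt[:, None], ct[None, :], rho)
    # inclusion–exclusion over the CDF grid
    p = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(p, 0.0, 1.0)


@dataclass
class PolychoricResult:
    """ML polychoric fit with profile CI and multiple-threshold GOF test."""

    rho_hat: Optional[float]
    rho_ci: tuple[Optional[float], Optional[float]]
    row_thresholds_hat: Optional[tuple[float, ...]]
    col_thresholds_hat: Optional[tuple[float, ...]]
    loglik: Optional[float]
    gof_chi2: Optional[float]
    gof_df: Optional[int]
    gof_p: Optional[float]
    n: float
    equal_thresholds: bool
    converged: bool
    estimable: bool = True
    reason: Optional[str] = None
    boundary: bool = False

    def format(self) -> str:
        if not self.estimable:
            return "—"
        lo, hi = self.rho_ci
        return f"{self.rho_hat:.2f} ({lo:.2f}–{hi:.2f})"


def _start_thresholds(margin: np.ndarray) -> np.ndarray:
    """Threshold starts from a margin's cumulative frequencies."""
    n = margin.sum()
    cum = np.cumsum(margin)[:-1] / n
    cum = np.clip(cum, 0.5 / n, 1.0 - 0.5 / n)
    return norm.ppf(cum)


def _pack(rho: float, rt: np.ndarray, ct: Optional[np.ndarray]) -> np.ndarray:
    def tpack(t):
        return np.concatenate(([t[0]], np.log(np.diff(t)))) if len(t) > 1 else np.array([t[0]])

    parts = [np.array([np.arctanh(np.clip(rho, -0.999, 0.999))]), tpack(rt)]
    if ct is not None:
        parts.append(tpack(ct))
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, k_r: int, k_c: Optional[int]):
    rho = np.tanh(theta[0])

    def tunpack(sub):
        return np.concatenate(([sub[0]], sub[0] + np.cumsum(np.exp(sub[1:])))) if len(sub) > 1 else sub

    rt = tunpack(theta[1 : 1 + k_r])
    ct = rt if k_c is None else tunpack(theta[1 + k_r : 1 + k_r + k_c])
    return rho, rt, ct


def fit_polychoric(
    table: PairTable,
    equal_thresholds_across_twins: bool = True,
    ci_level: float = 0.95,
    compute_ci: bool = True,
) -> PolychoricResult:
    """Joint-ML polychoric correlation for a co-twin contingency table.

    When ``equal_thresholds_across_twins`` is set (the default, the
    exchangeable-twins reporting model for same-sex groups) one shared
    set of cutpoints applies to both margins; otherwise each margin has
    its own.  Returns a non-estimable result when a margin has fewer
    than two non-empty categories (rho is then not identified).
    """
    counts = table.counts
    k = counts.shape[0]
    n = counts.sum()
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)

    def dead(reason: str) -> PolychoricResult:
        return PolychoricResult(None, (None, None), None, None, None, None, None,
                                None, float(n), equal_thresholds_across_twins,
                                converged=False, estimable=False, reason=reason)

    if (row_m > 0).sum() < 2 or (col_m > 0).sum() < 2:
        return dead("margin with fewer than two non-empty categories")

    k_thr = k - 1
    shared = equal_thresholds_across_twins

    def nll(theta: np.ndarray) -> float:
        rho, rt, ct = _unpack(theta, k_thr, None if shared else k_thr)
        if abs(rho) > 0.999999:
            return 1e12
        p = bvn_cell_probs(rho, rt, ct)
        return -float(np.sum(counts * np.log(np.maximum(p, _TINY))))

    rt0 = _start_thresholds((row_m + col_m) / 2.0 if shared else row_m)
    ct0 = None if shared else _start_thresholds(col_m)
    best = None
    for rho0 in (0.0, 0.4, -0.4, 0.8):
        theta0 = _pack(rho0, rt0, ct0)
        res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    assert best is not None
    rho_hat, rt_hat, ct_hat = _unpack(best.x, k_thr, None if shared else k_thr)
    loglik = -best.fun
    boundary = abs(rho_hat) > 0.9999

    # profile-likelihood CI for rho
    crit = chi2_dist.ppf(ci_level, 1)

    def profile_nll(rho_fix: float) -> float:
        def nll_t(sub: np.ndarray) -> float:
            theta = np.concatenate(([np.arctanh(np.clip(rho_fix, -0.999999, 0.999999))], sub))
            return nll(theta)

        sub0 = _pack(rho_hat, rt_hat, ct_hat)[1:]
        r = optimize.minimize(nll_t, sub0, method="L-BFGS-B",
                              options={"maxiter": 300, "ftol": 1e-12})
        return r.fun

    def dev(rho_fix: float) -> float:
        return 2.0 * (profile_nll(rho_fix) - (-loglik)) - crit

    def _ci_bound(direction: int) -> float:
        """Walk outward from rho_hat until the profile deviance crosses crit."""
        limit = -0.9999 if direction < 0 else 0.9999
        span = abs(limit - rho_hat)
        step = max(0.02, span / 16)
        x = rho_hat
        while abs(limit - (x + direction * step)) > 1e-12 and \
                (limit - (x + direction * step)) * direction > 0:
            nxt = x + direction * step
            if dev(nxt) >= 0:
                a, b = sorted((x, nxt))
                return float(optimize.brentq(dev, a, b, xtol=1e-5))
            x = nxt
        return -1.0 if direction < 0 else 1.0

    lo: Optional[float] = None
    hi: Optional[float] = None
    if compute_ci:
        try:
            lo = _ci_bound(-1)
            hi = _ci_bound(+1)
        except ValueError:
            lo, hi = None, None

    result = PolychoricResult(
        rho_hat=float(rho_hat),
        rho_ci=(lo, hi),
        row_thresholds_hat=tuple(float(t) for t in rt_hat),
        col_thresholds_hat=tuple(float(t) for t in ct_hat),
        loglik=float(loglik),
        gof_chi2=None,
        gof_df=None,
        gof_p=None,
        n=float(n),
        equal_thresholds=shared,
        converged=bool(best.success),
        boundary=boundary,
    )
    chi2_val, df, p = multiple_threshold_gof(table, result)
    result.gof_chi2, result.gof_df, result.gof_p = chi2_val, df, p
    return result


def multiple_threshold_gof(table: PairTable, fit: PolychoricResult):
    """Chi-square goodness of fit of the single-liability-continuum model.

    chi2 = sum (O - E)^2 / E over cells with E = n * p(rho_hat, t_hat);
    df = (k^2 - 1) - (#free thresholds + 1).  A fitted cell probability
    of (numerically) zero where a count was observed makes the statistic
    undefined and returns (None, df, None).
    """
    if not fit.estimable or fit.rho_hat is None:
        return None, None, None
    counts = table.counts
    k = counts.shape[0]
    n = counts.sum()
    p = bvn_cell_probs(fit.rho_hat, fit.row_thresholds_hat, fit.col_thresholds_hat)
    expected = n * p
    n_thr = (k - 1) if fit.equal_thresholds else 2 * (k - 1)
    df = (k * k - 1) - (n_thr + 1)
    if np.any((expected < 1e-12) & (counts > 0)):
        return None, df, None
    mask = expected > 1e-12
    chi2_val = float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))
    p_val = float(chi2_dist.sf(chi2_val, df)) if df > 0 else None
    return chi2_val, df, p_val
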