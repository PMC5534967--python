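"""Ordinal twin variance-component (ACE/ADE) model fitting by full ML.

The observed ordinal status of each twin is the discretisation of a
standard-normal liability; liability variance decomposes into additive
genetic (A), common-environment (C) or dominance (D), and unique
environment (E) proportions.  MZ pairs have latent correlation
a2 + c2 + d2, DZ pairs 0.5*a2 + c2 + 0.25*d2.  C and D cannot be fitted
together from twin pairs alone, so the valid models are exactly
ACE, ADE, AE, CE and E.

Fitting maximises the sum of per-pair bivariate-normal rectangle
log-likelihoods over standardized variance proportions, thresholds and
optional linear age/sex threshold shifts.  Proportions are parametrised
through square-root path coefficients normalised to sum to one, which
keeps every estimate inside the unit simplex without explicit
constraints.  Nested models are compared by the likelihood-ratio
chi-square test and by AIC = -2LL + 2 * (free parameters); confidence
intervals for variance proportions are profile-likelihood based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from ._bvn import bvn_cdf
from .familial_clustering import COLLAPSE_RULES
from .liability_correlation import bvn_cell_probs
from .synthetic_cohort import TwinPairRecord

__all__ = [
    "ModelSpec",
    "BiometricFit",
    "LRTResult",
    "ParamSet",
    "pair_loglik",
    "fit_model",
    "likelihood_ratio_test",
    "aic",
    "profile_ci",
    "MODEL_LADDER",
]

_VALID_MODELS = {
    frozenset("ACE"), frozenset("ADE"), frozenset("AE"), frozenset("CE"), frozenset("E"),
}

#: Reporting order of the standard nested-model ladder.
MODEL_LADDER = ("ACE", "AE", "CE", "E", "ADE")

_TINY = 1e-300


@dataclass(frozen=True)
class ModelSpec:
    """Which variance components, covariates and category count to fit."""

    components: str = "ACE"
    covariates: tuple[str, ...] = ()
    n_categories: int = 3

    def __post_init__(self) -> None:
        comp = frozenset(self.components.upper())
        if comp not in _VALID_MODELS:
            raise ValueError(
                f"invalid model {self.components!r}; valid: ACE, ADE, AE, CE, E"
            )
        object.__setattr__(self, "components", "".join(
            c for c in "ACDE" if c in comp))
        for cov in self.covariates:
            if cov not in ("age", "sex"):
                raise ValueError(f"unknown covariate {cov!r}")
        if self.n_categories not in (2, 3):
            raise ValueError("n_categories must be 2 or 3")

    @property
    def free_components(self) -> tuple[str, ...]:
        return tuple(c for c in self.components if c != "E")

    @property
    def n_free_params(self) -> int:
        return len(self.free_components) + (self.n_categories - 1) + len(self.covariates)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            set(self.components) <= set(other.components)
            and self.covariates == other.covariates
            and self.n_categories == other.n_categories
        )


@dataclass(frozen=True)
class ParamSet:
    """A concrete parameter point of the liability model."""

    a2: float
    c2: float
    d2: float
    thresholds: tuple[float, ...]
    beta_age: float = 0.0
    beta_sex: float = 0.0
    age_ref: float = 0.0

    @property
    def e2(self) -> float:
        return 1.0 - self.a2 - self.c2 - self.d2

    @property
    def r_mz(self) -> float:
        return self.a2 + self.c2 + self.d2

    @property
    def r_dz(self) -> float:
        return 0.5 * self.a2 + self.c2 + 0.25 * self.d2


@dataclass
class LRTResult:
    """Likelihood-ratio chi-square comparison of two nested fits."""

    chi2: float
    df: int
    p: float
    warning: Optional[str] = None


@dataclass
class BiometricFit:
    """A fitted twin variance-component model."""

    spec: ModelSpec
    estimates: dict[str, float]
    minus2LL: float
    aic: float
    params: Optional[ParamSet] = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True
    n_pairs_by_group: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_minus2ll(cls, components: str, minus2LL: float,
                      n_categories: int = 3) -> "BiometricFit":
        """Minimal fit object from a known -2LL (for model-comparison use)."""
        spec = ModelSpec(components=components, n_categories=n_categories)
        return cls(spec=spec, estimates={}, minus2LL=float(minus2LL),
                   aic=float(minus2LL) + 2 * spec.n_free_params)


# ---------------------------------------------------------------------------
# Likelihood


def _rect_logprob(lo1, hi1, lo2, hi2, rho: float) -> np.ndarray:
    p = (
        bvn_cdf(hi1, hi2, rho)
        - bvn_cdf(lo1, hi2, rho)
        - bvn_cdf(hi1, lo2, rho)
        + bvn_cdf(lo1, lo2, rho)
    )
    return np.log(np.maximum(p, _TINY))


def pair_loglik(record: TwinPairRecord, spec: ModelSpec, params: ParamSet) -> float:
    """Log-probability of one twin pair's observed status pair.

    The pair's liabilities are bivariate normal with the zygosity-implied
    correlation; each twin's status defines a liability rectangle between
    consecutive (covariate-shifted) thresholds.
    """
    t = np.asarray(params.thresholds, dtype=float)
    k = len(t) + 1
    rho = params.r_mz if record.is_mz else params.r_dz
    bounds = []
    for status, sex in ((record.status1, record.sex1), (record.status2, record.sex2)):
        if not 0 <= status < k:
            raise ValueError(f"status {status} outside 0..{k - 1}")
        shift = params.beta_age * (record.age - params.age_ref)
        shift += params.beta_sex * (1.0 if sex == "M" else 0.0)
        ts = t + shift
        lo = -np.inf if status == 0 else ts[status - 1]
        hi = np.inf if status == k - 1 else ts[status]
        bounds.append((lo, hi))
    (lo1, hi1), (lo2, hi2) = bounds
    return float(_rect_logprob(lo1, hi1, lo2, hi2, rho))


class _Prepared:
    """Records reduced to the arrays/tables the likelihood needs."""

    def __init__(self, records: Sequence[TwinPairRecord], k: int,
                 collapse: dict[int, Optional[int]], covariates: tuple[str, ...],
                 exclusion: str = "pair"):
        self.k = k
        self.covariates = covariates
        s1, s2, age, m1, m2, mz = [], [], [], [], [], []
        sing_s, sing_age, sing_m, n_dropped = [], [], [], 0
        groups: dict[str, int] = {}
        for rec in records:
            c1, c2 = collapse[rec.status1], collapse[rec.status2]
            if c1 is None or c2 is None:
                if exclusion == "pair" or (c1 is None and c2 is None):
                    n_dropped += 1
                    continue
                st, sx = (c2, rec.sex2) if c1 is None else (c1, rec.sex1)
                sing_s.append(st)
                sing_age.append(rec.age)
                sing_m.append(1.0 if sx == "M" else 0.0)
                continue
            s1.append(c1)
            s2.append(c2)
            age.append(rec.age)
            m1.append(1.0 if rec.sex1 == "M" else 0.0)
            m2.append(1.0 if rec.sex2 == "M" else 0.0)
            mz.append(rec.is_mz)
            groups[rec.zygosity_group] = groups.get(rec.zygosity_group, 0) + 1
        if not s1:
            raise ValueError("no usable pairs after classification")
        self.s1 = np.array(s1, dtype=int)
        self.s2 = np.array(s2, dtype=int)
        self.age = np.array(age, dtype=float)
        self.m1 = np.array(m1)
        self.m2 = np.array(m2)
        self.mz = np.array(mz, dtype=bool)
        self.sing_s = np.array(sing_s, dtype=int)
        self.sing_age = np.array(sing_age, dtype=float)
        self.sing_m = np.array(sing_m, dtype=float)
        self.n_dropped = n_dropped
        self.groups = groups
        ages = np.concatenate([self.age, self.sing_age]) if len(sing_s) else self.age
        self.age_ref = float(ages.mean())
        self.has_cov = bool(covariates)
        if not self.has_cov:
            self.mz_counts = np.zeros((k, k))
            self.dz_counts = np.zeros((k, k))
            np.add.at(self.mz_counts, (self.s1[self.mz], self.s2[self.mz]), 1.0)
            np.add.at(self.dz_counts, (self.s1[~self.mz], self.s2[~self.mz]), 1.0)
            self.sing_counts = np.bincount(self.sing_s, minlength=k).astype(float)

    def neg_loglik(self, p: ParamSet) -> float:
        k = self.k
        t = np.asarray(p.thresholds)
        if not self.has_cov:
            ll = 0.0
            for counts, rho in ((self.mz_counts, p.r_mz), (self.dz_counts, p.r_dz)):
                if counts.sum() > 0:
                    probs = bvn_cell_probs(rho, t, t)
                    ll += float(np.sum(counts * np.log(np.maximum(probs, _TINY))))
            if self.sing_counts.sum() > 0:
                cum = np.concatenate(([0.0], norm.cdf(t), [1.0]))
                marg = np.diff(cum)
                ll += float(np.sum(self.sing_counts * np.log(np.maximum(marg, _TINY))))
            return -ll

        shift1 = p.beta_age * (self.age - p.age_ref) + p.beta_sex * self.m1
        shift2 = p.beta_age * (self.age - p.age_ref) + p.beta_sex * self.m2
        ext = np.concatenate(([-np.inf], t, [np.inf]))
        lo1 = ext[self.s1] + np.where(self.s1 == 0, 0.0, shift1)
        hi1 = ext[self.s1 + 1] + np.where(self.s1 == k - 1, 0.0, shift1)
        lo2 = ext[self.s2] + np.where(self.s2 == 0, 0.0, shift2)
        hi2 = ext[self.s2 + 1] + np.where(self.s2 == k - 1, 0.0, shift2)
        ll = 0.0
        for mask, rho in ((self.mz, p.r_mz), (~self.mz, p.r_dz)):
            if mask.any():
                ll += float(
                    _rect_logprob(lo1[mask], hi1[mask], lo2[mask], hi2[mask], rho).sum()
                )
        if len(self.sing_s):
            sh = p.beta_age * (self.sing_age - p.age_ref) + p.beta_sex * self.sing_m
            lo = ext[self.sing_s] + np.where(self.sing_s == 0, 0.0, sh)
            hi = ext[self.sing_s + 1] + np.where(self.sing_s == k - 1, 0.0, sh)
            ll += float(np.log(np.maximum(norm.cdf(hi) - norm.cdf(lo), _TINY)).sum())
        return -ll


def _proportions_from_u(u: np.ndarray, comps: tuple[str, ...]) -> dict[str, float]:
    denom = 1.0 + float(np.sum(u * u))
    out = {"A": 0.0, "C": 0.0, "D": 0.0}
    for ui, c in zip(u, comps):
        out[c] = float(ui * ui) / denom
    return out


def _paramset(theta: np.ndarray, spec: ModelSpec, age_ref: float) -> ParamSet:
    comps = spec.free_components
    nv = len(comps)
    k_thr = spec.n_categories - 1
    props = _proportions_from_u(theta[:nv], comps)
    sub = theta[nv : nv + k_thr]
    t = np.concatenate(([sub[0]], sub[0] + np.cumsum(np.exp(sub[1:])))) if k_thr > 1 else sub
    i = nv + k_thr
    beta_age = beta_sex = 0.0
    if "age" in spec.covariates:
        beta_age = float(theta[i]); i += 1
    if "sex" in spec.covariates:
        beta_sex = float(theta[i]); i += 1
    return ParamSet(
        a2=props["A"], c2=props["C"], d2=props["D"],
        thresholds=tuple(float(x) for x in t),
        beta_age=beta_age, beta_sex=beta_sex, age_ref=age_ref,
    )


def _pack_thresholds(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.concatenate(([t[0]], np.log(np.diff(t)))) if len(t) > 1 else t


# Fixed variance-proportion starting points spanning the simplex, as
# (first, second) free-component proportions; the second entry is
# ignored for single-component models.
_STARTS = ((0.3, 0.2), (0.6, 0.05), (0.05, 0.6), (0.15, 0.15), (0.45, 0.4))


def _threshold_start(prep: _Prepared) -> np.ndarray:
    k = prep.k
    counts = np.zeros(k)
    for s in (prep.s1, prep.s2):
        counts += np.bincount(s, minlength=k)
    if len(prep.sing_s):
        counts += np.bincount(prep.sing_s, minlength=k)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-4, 1 - 1e-4)
    return norm.ppf(cum)


def fit_model(
    records: Sequence[TwinPairRecord],
    spec: ModelSpec,
    collapse: str | dict[int, Optional[int]] | None = None,
    exclusion: str = "pair",
    compute_ci: bool = False,
    ci_level: float = 0.95,
) -> BiometricFit:
    """Fit an ordinal twin variance-component model by full ML.

    ``collapse`` maps raw 3-category statuses to the analysis categories
    (defaults to "three" or "two" according to ``spec.n_categories``);
    ``exclusion`` says whether a pair with one excluded twin is dropped
    entirely ("pair") or keeps the remaining twin's marginal likelihood
    ("individual").  Optimisation is quasi-Newton from five fixed
    variance-proportion starts, so the result is deterministic.
    """
    if collapse is None:
        collapse = "three" if spec.n_categories == 3 else "two"
    rule = COLLAPSE_RULES[collapse] if isinstance(collapse, str) else collapse
    k_rule = len(set(v for v in rule.values() if v is not None))
    if k_rule != spec.n_categories:
        raise ValueError(
            f"collapse rule yields {k_rule} categories but spec expects {spec.n_categories}"
        )
    prep = _Prepared(records, spec.n_categories, rule, spec.covariates, exclusion)
    comps = spec.free_components
    if comps and not (prep.mz.any() and (~prep.mz).any()):
        raise ValueError("models with A, C or D need both MZ and DZ pairs")

    t0 = _pack_thresholds(_threshold_start(prep))
    beta0 = [0.0] * len(spec.covariates)

    def nll(theta: np.ndarray) -> float:
        return prep.neg_loglik(_paramset(theta, spec, prep.age_ref))

    if not comps:  # E model: no variance parameters
        starts = [np.concatenate(([], t0, beta0))]
    else:
        starts = []
        for p1, p2 in _STARTS:
            props = (p1,) if len(comps) == 1 else (p1, p2)
            e2 = 1.0 - sum(props)
            u0 = np.sqrt(np.array(props) / e2)
            starts.append(np.concatenate((u0, t0, beta0)))

    best = None
    for theta0 in starts:
        res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                                options={"maxiter": 1000, "ftol": 1e-11, "gtol": 1e-7})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    assert best is not None
    params = _paramset(best.x, spec, prep.age_ref)
    m2ll = 2.0 * best.fun
    estimates = {"a2": params.a2, "c2": params.c2, "d2": params.d2, "e2": params.e2}
    fit = BiometricFit(
        spec=spec,
        estimates=estimates,
        minus2LL=float(m2ll),
        aic=float(m2ll + 2 * spec.n_free_params),
        params=params,
        converged=bool(best.success),
        n_pairs_by_group=prep.groups,
    )
    if compute_ci:
        for comp in comps:
            key = {"A": "a2", "C": "c2", "D": "d2"}[comp]
            fit.ci[key] = profile_ci(records, fit, key, level=ci_level,
                                     collapse=collapse, exclusion=exclusion)
        fit.ci["e2"] = profile_ci(records, fit, "e2", level=ci_level,
                                  collapse=collapse, exclusion=exclusion)
    return fit


def aic(fit: BiometricFit) -> float:
    """AIC = -2LL + 2 x (free parameters); lower is more parsimonious."""
    return fit.minus2LL + 2 * fit.spec.n_free_params


def likelihood_ratio_test(full: BiometricFit, nested: BiometricFit) -> LRTResult:
    """Likelihood-ratio chi-square test of a nested against a full model.

    chi2 is the -2LL difference, df the difference in free variance
    parameters, p the upper-tail central chi-square probability.  A tiny
    negative chi2 from numerics is clamped to zero with a warning.
    """
    if not nested.spec.is_nested_in(full.spec):
        raise ValueError(
            f"{nested.spec.components} is not nested in {full.spec.components}"
        )
    df = len(full.spec.free_components) - len(nested.spec.free_components)
    if df <= 0:
        raise ValueError("nested model must have fewer free parameters")
    chi2_val = nested.minus2LL - full.minus2LL
    warning = None
    if chi2_val < 0:
        warning = f"negative chi2 {chi2_val:.3g} clamped to 0"
        chi2_val = 0.0
    return LRTResult(chi2=float(chi2_val), df=df,
                     p=float(chi2_dist.sf(chi2_val, df)), warning=warning)


def profile_ci(
    records: Sequence[TwinPairRecord],
    fit: BiometricFit,
    component: str,
    level: float = 0.95,
    collapse: str | dict[int, Optional[int]] | None = None,
    exclusion: str = "pair",
) -> tuple[float, float]:
    """Profile-likelihood CI for one variance proportion.

    Endpoints are where the profiled -2LL rises by the chi-square(1)
    quantile (3.84 at 95%) above its minimum, clamped to [0, 1]; an
    endpoint that never brackets within the unit interval is reported at
    the boundary.
    """
    spec = fit.spec
    if collapse is None:
        collapse = "three" if spec.n_categories == 3 else "two"
    rule = COLLAPSE_RULES[collapse] if isinstance(collapse, str) else collapse
    prep = _Prepared(records, spec.n_categories, rule, spec.covariates, exclusion)
    comps = spec.free_components
    key_of = {"A": "a2", "C": "c2", "D": "d2"}
    valid = [key_of[c] for c in comps] + ["e2"]
    if component not in valid:
        raise ValueError(f"component {component!r} not in model {spec.components}")
    crit = chi2_dist.ppf(level, 1)
    point = fit.estimates[component]
    m2ll_min = fit.minus2LL

    # component proportions under the constraint: the profiled component is
    # fixed at v; remaining mass splits among the other free components via
    # a sigmoid weight when two remain.
    others = [c for c in comps if key_of[c] != component]
    # one sigmoid weight splits the remaining mass when two proportions
    # stay free under the constraint, otherwise none is needed
    if component == "e2":
        n_w = 1 if len(others) == 2 else 0
    else:
        n_w = 1 if len(others) == 1 else 0

    k_thr = spec.n_categories - 1
    t_hat = _pack_thresholds(np.asarray(fit.params.thresholds))
    beta_hat = []
    if "age" in spec.covariates:
        beta_hat.append(fit.params.beta_age)
    if "sex" in spec.covariates:
        beta_hat.append(fit.params.beta_sex)

    def profile_m2ll(v: float) -> float:
        v = min(max(v, 0.0), 1.0)

        def build(props_free: dict[str, float], sub: np.ndarray) -> ParamSet:
            t = (np.concatenate(([sub[0]], sub[0] + np.cumsum(np.exp(sub[1:]))))
                 if k_thr > 1 else sub[:1])
            i = k_thr
            ba = bs = 0.0
            if "age" in spec.covariates:
                ba = float(sub[i]); i += 1
            if "sex" in spec.covariates:
                bs = float(sub[i]); i += 1
            return ParamSet(a2=props_free.get("a2", 0.0), c2=props_free.get("c2", 0.0),
                            d2=props_free.get("d2", 0.0),
                            thresholds=tuple(float(x) for x in t),
                            beta_age=ba, beta_sex=bs, age_ref=prep.age_ref)

        def nll_sub(x: np.ndarray) -> float:
            w_par = x[:n_w]
            sub = x[n_w:]
            props: dict[str, float] = {}
            if component == "e2":
                rest = 1.0 - v
                if len(others) == 0:
                    pass
                elif len(others) == 1:
                    props[key_of[others[0]]] = rest
                else:
                    w = 1.0 / (1.0 + math.exp(-float(w_par[0])))
                    props[key_of[others[0]]] = rest * w
                    props[key_of[others[1]]] = rest * (1.0 - w)
            else:
                props[component] = v
                if len(others) == 1:
                    w = 1.0 / (1.0 + math.exp(-float(w_par[0])))
                    props[key_of[others[0]]] = (1.0 - v) * w
            return prep.neg_loglik(build(props, sub))

        x0 = np.concatenate((np.zeros(n_w), t_hat, beta_hat))
        res = optimize.minimize(nll_sub, x0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-11})
        return 2.0 * res.fun

    def excess(v: float) -> float:
        return profile_m2ll(v) - (m2ll_min + crit)

    def bound(direction: int) -> float:
        limit = 0.0 if direction < 0 else 1.0
        x = point
        step = max(0.02, abs(limit - point) / 12)
        while (limit - (x + direction * step)) * direction > 1e-12:
            nxt = x + direction * step
            if excess(nxt) >= 0:
                a, b = sorted((x, nxt))
                return float(optimize.brentq(excess, a, b, xtol=1e-4))
            x = nxt
        if excess(limit) >= 0 and abs(limit - x) > 1e-12:
            a, b = sorted((x, limit))
            return float(optimize.brentq(excess, a, b, xtol=1e-4))
        return limit

    return (bound(-1), bound(+1))
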