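"""Synthetic twin-cohort generation under the liability-threshold model.

Depression status (non-depressed / minor / major) is modelled as the
discretisation of an unobserved standard-normal liability.  Twin pairs
share liability through additive-genetic (A), common-environment (C) or
dominance (D) components, giving latent correlations

    r_MZ = a2 + c2 + d2,      r_DZ = 0.5*a2 + c2 + 0.25*d2.

Age and sex act as linear shifts of the category thresholds on the
probit scale (equivalently, of the liability mean with sign flipped);
the same shift applies to every threshold, so category boundaries move
in parallel.

Two presets mirror the structure of the cohorts this package is designed
around: an older-adult cohort ("aged", 643 MZ + 577 DZ pairs, ages
50–92, current-depression prevalences 8.98% minor / 2.05% major) and a
young-adult cohort ("te", 1005 MZ + 1358 DZ pairs, ages 23–38, lifetime
prevalences 7.70% minor / 37.41% major).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "SimulationParams",
    "TwinPairRecord",
    "ZYGOSITY_GROUPS",
    "classify_dsm",
    "liability_to_status",
    "simulate_cohort",
    "thresholds_from_prevalences",
    "preset_params",
]

#: Zygosity/sex groups; the two letters give (sex of twin 1, sex of twin 2).
ZYGOSITY_GROUPS = ("MZ-FF", "MZ-MM", "DZ-FF", "DZ-MM", "DZ-FM", "DZ-MF")

_N_SYMPTOMS = 9  # DSM-IV major-depressive-episode criteria; 1-2 are core


def classify_dsm(symptoms: Sequence[int]) -> int:
    """Classify a 9-item DSM-IV symptom indicator vector.

    Positions 1 and 2 are the core symptoms (depressed mood, anhedonia).
    Returns 2 (major depression) for >= 5 symptoms including a core
    symptom, 1 (minor depression) for 2-4 symptoms including a core
    symptom, else 0 (non-depressed).
    """
    v = np.asarray(symptoms)
    if v.shape != (_N_SYMPTOMS,):
        raise ValueError(f"expected {_N_SYMPTOMS} symptom indicators, got shape {v.shape}")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("symptom indicators must be 0/1")
    total = int(v.sum())
    core = bool(v[0] or v[1])
    if core and total >= 5:
        return 2
    if core and 2 <= total <= 4:
        return 1
    return 0


def thresholds_from_prevalences(prev_minor: float, prev_major: float) -> tuple[float, float]:
    """Liability cutpoints (t1, t2) from category prevalences.

    ``prev_minor``/``prev_major`` are the marginal probabilities of minor
    and major depression; t1 separates non-depressed from minor-or-major,
    t2 separates minor from major.
    """
    p_any = prev_minor + prev_major
    if not (0.0 < prev_major < p_any < 1.0):
        raise ValueError("prevalences must be positive and sum to less than 1")
    return float(norm.ppf(1.0 - p_any)), float(norm.ppf(1.0 - prev_major))


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters for a simulated twin cohort.

    Variance proportions ``a2``/``c2``/``d2``/``e2`` must be non-negative
    and sum to 1; C and D may not both be positive (an ACDE model is not
    identifiable from twin pairs alone).  ``thresholds`` are ordered
    liability cutpoints in standard-normal units; ``beta_age`` (per year)
    and ``beta_sex`` (male vs female) shift all thresholds linearly on
    the probit scale.
    """

    a2: float = 0.47
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 0.53
    thresholds: tuple[float, ...] = (1.2249, 2.0433)
    beta_age: float = 0.0
    beta_sex: float = 0.0
    n_pairs_by_group: dict[str, int] = field(
        default_factory=lambda: {g: 100 for g in ZYGOSITY_GROUPS}
    )
    age_range: tuple[float, float] = (50.0, 92.0)
    seed: int = 0
    with_symptoms: bool = False

    def __post_init__(self) -> None:
        comps = (self.a2, self.c2, self.d2, self.e2)
        if any(c < 0 for c in comps):
            raise ValueError("variance components must be non-negative")
        if abs(sum(comps) - 1.0) > 1e-12:
            raise ValueError(f"variance components must sum to 1, got {sum(comps)}")
        if self.c2 > 0 and self.d2 > 0:
            raise ValueError("c2 and d2 may not both be positive (ACE or ADE only)")
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be non-empty and strictly increasing")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max)")
        for g in self.n_pairs_by_group:
            if g not in ZYGOSITY_GROUPS:
                raise ValueError(f"unknown zygosity group {g!r}")

    @property
    def r_mz(self) -> float:
        return self.a2 + self.c2 + self.d2

    @property
    def r_dz(self) -> float:
        return 0.5 * self.a2 + self.c2 + 0.25 * self.d2


@dataclass(frozen=True)
class TwinPairRecord:
    """One twin pair: zygosity/sex group, shared age, per-twin status."""

    pair_id: str
    zygosity_group: str
    age: float
    status1: int
    status2: int
    symptoms1: Optional[tuple[int, ...]] = None
    symptoms2: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.zygosity_group not in ZYGOSITY_GROUPS:
            raise ValueError(f"unknown zygosity group {self.zygosity_group!r}")
        for s in (self.status1, self.status2):
            if s not in (0, 1, 2):
                raise ValueError(f"status must be 0, 1 or 2, got {s}")

    @property
    def is_mz(self) -> bool:
        return self.zygosity_group.startswith("MZ")

    @property
    def sex1(self) -> str:
        return self.zygosity_group[3]

    @property
    def sex2(self) -> str:
        return self.zygosity_group[4]

    @property
    def same_sex(self) -> bool:
        return self.sex1 == self.sex2


def liability_to_status(
    liability: float,
    thresholds: Sequence[float],
    age: float = 0.0,
    sex: int = 0,
    beta_age: float = 0.0,
    beta_sex: float = 0.0,
    age_ref: float = 0.0,
) -> int:
    """Ordinal status implied by a liability value and shifted cutpoints.

    The status is the number of shifted thresholds strictly below the
    liability; a liability exactly at a cutpoint falls in the lower
    category.  ``sex`` is 1 for male, 0 for female; ``age_ref`` is the
    cohort mean age so the age effect is centred.
    """
    t = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    shifted = t + beta_age * (age - age_ref) + beta_sex * sex
    return int(np.sum(shifted < liability))


def _shifted_thresholds(params: SimulationParams, age: np.ndarray, male: np.ndarray) -> np.ndarray:
    age_ref = 0.5 * (params.age_range[0] + params.age_range[1])
    t = np.asarray(params.thresholds, dtype=float)
    return t[None, :] + (params.beta_age * (age - age_ref) + params.beta_sex * male)[:, None]


def _statuses(liab: np.ndarray, shifted: np.ndarray) -> np.ndarray:
    return (shifted < liab[:, None]).sum(axis=1).astype(int)


def _symptom_vector(rng: np.random.Generator, status: int) -> tuple[int, ...]:
    """Draw a symptom vector consistent with a status category.

    Counts are drawn uniformly over the category-consistent range and a
    core symptom is forced for minor/major; only the classification rule,
    not the symptom distribution itself, is scientifically constrained.
    """
    v = np.zeros(_N_SYMPTOMS, dtype=int)
    if status == 0:
        count = int(rng.integers(0, 2))  # 0 or 1 symptoms, any position
        pos = rng.choice(_N_SYMPTOMS, size=count, replace=False)
        v[pos] = 1
    else:
        count = int(rng.integers(2, 5)) if status == 1 else int(rng.integers(5, 10))
        core = int(rng.integers(0, 2))
        others = np.delete(np.arange(_N_SYMPTOMS), core)
        rest = rng.choice(others, size=count - 1, replace=False)
        v[core] = 1
        v[rest] = 1
    return tuple(int(x) for x in v)


def simulate_cohort(params: SimulationParams) -> list[TwinPairRecord]:
    """Simulate twin pairs under the bivariate-normal liability model.

    Liabilities for a pair are bivariate standard normal with correlation
    ``r_MZ`` or ``r_DZ``; both co-twins share the pair's age.  The output
    is deterministic for a given ``params.seed`` and group sizes match
    ``n_pairs_by_group`` exactly.
    """
    rng = np.random.default_rng(params.seed)
    records: list[TwinPairRecord] = []
    for group in ZYGOSITY_GROUPS:
        n = params.n_pairs_by_group.get(group, 0)
        if n == 0:
            continue
        r = params.r_mz if group.startswith("MZ") else params.r_dz
        age = rng.uniform(params.age_range[0], params.age_range[1], size=n)
        z = rng.standard_normal((n, 2))
        l1 = z[:, 0]
        l2 = r * z[:, 0] + np.sqrt(max(0.0, 1.0 - r * r)) * z[:, 1]
        male1 = np.full(n, 1.0 if group[3] == "M" else 0.0)
        male2 = np.full(n, 1.0 if group[4] == "M" else 0.0)
        s1 = _statuses(l1, _shifted_thresholds(params, age, male1))
        s2 = _statuses(l2, _shifted_thresholds(params, age, male2))
        for i in range(n):
            sym1 = sym2 = None
            if params.with_symptoms:
                sym1 = _symptom_vector(rng, int(s1[i]))
                sym2 = _symptom_vector(rng, int(s2[i]))
            records.append(
                TwinPairRecord(
                    pair_id=f"{group}-{i:05d}",
                    zygosity_group=group,
                    age=float(age[i]),
                    status1=int(s1[i]),
                    status2=int(s2[i]),
                    symptoms1=sym1,
                    symptoms2=sym2,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Cohort presets

_AGED_GROUPS = {"MZ-FF": 491, "MZ-MM": 152, "DZ-FF": 263, "DZ-MM": 73, "DZ-FM": 136, "DZ-MF": 105}
_TE_GROUPS = {"MZ-FF": 609, "MZ-MM": 396, "DZ-FF": 455, "DZ-MM": 349, "DZ-FM": 301, "DZ-MF": 253}


def _sex_threshold_gap(prev_any_f: float, prev_any_m: float) -> float:
    """Probit-scale male-vs-female shift implied by two-category prevalences."""
    return float(norm.ppf(1.0 - prev_any_m) - norm.ppf(1.0 - prev_any_f))


def preset_params(name: str, seed: int = 0, with_symptoms: bool = False) -> SimulationParams:
    """Generating parameters for the two built-in cohort presets.

    ``aged``: 1220 pairs, ages 50–92, minor/major prevalences
    8.98%/2.05%, AE liability model with a2 = 0.47 (the older-cohort
    three-category heritability).  ``te``: 2363 pairs, ages 23–38,
    prevalences 7.70%/37.41%, a2 = 0.40.  Sex threshold shifts are set
    from the sex-specific two-category prevalences; no age trend is
    imposed by default.
    """
    if name == "aged":
        return SimulationParams(
            a2=0.47,
            e2=0.53,
            thresholds=thresholds_from_prevalences(0.0898, 0.0205),
            beta_sex=_sex_threshold_gap(0.1172, 0.0926),
            n_pairs_by_group=dict(_AGED_GROUPS),
            age_range=(50.0, 92.0),
            seed=seed,
            with_symptoms=with_symptoms,
        )
    if name == "te":
        return SimulationParams(
            a2=0.40,
            e2=0.60,
            thresholds=thresholds_from_prevalences(0.0770, 0.3741),
            beta_sex=_sex_threshold_gap(0.5004, 0.3865),
            n_pairs_by_group=dict(_TE_GROUPS),
            age_range=(23.0, 38.0),
            seed=seed,
            with_symptoms=with_symptoms,
        )
    raise ValueError(f"unknown preset {name!r} (expected 'aged' or 'te')")


def with_components(params: SimulationParams, a2: float, c2: float = 0.0, d2: float = 0.0) -> SimulationParams:
    """Copy of ``params`` with a different variance decomposition."""
    e2 = 1.0 - a2 - c2 - d2
    return replace(params, a2=a2, c2=c2, d2=d2, e2=e2)
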