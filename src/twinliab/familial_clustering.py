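"""Proband -> co-twin relative risks by zygosity group.

Familial clustering of an ordinal phenotype is summarised by the
relative risk (RR): the co-twin's risk of an outcome given an affected
proband, divided by the co-twin's risk given a non-depressed proband.
Same-sex pair tables are first made symmetric by averaging over the
choice of proband (half-sum of the table and its transpose), which uses
each pair once and keeps confidence intervals honest.  Confidence
intervals use the Katz log-RR normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .synthetic_cohort import TwinPairRecord

__all__ = [
    "PairTable",
    "RelativeRiskEstimate",
    "crosstab",
    "symmetrize",
    "relative_risk",
    "COLLAPSE_RULES",
]

#: Named status-collapse rules mapping the 3-category status onto analysis
#: categories.  "three": keep all; "two": merge minor and major;
#: "minor-only"/"major-only": drop pairs containing the excluded category.
COLLAPSE_RULES: dict[str, dict[int, Optional[int]]] = {
    "three": {0: 0, 1: 1, 2: 2},
    "two": {0: 0, 1: 1, 2: 1},
    "minor-only": {0: 0, 1: 1, 2: None},
    "major-only": {0: 0, 1: None, 2: 1},
}


@dataclass
class PairTable:
    """k x k co-twin status contingency table for one zygosity grouping.

    Rows index the proband (twin 1) status, columns the co-twin (twin 2)
    status.  Counts may be half-integers after symmetrization.
    """

    counts: np.ndarray
    category_labels: tuple[str, ...]
    zygosity_group: str
    same_sex: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.category_labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if k not in (2, 3):
            raise ValueError("2 or 3 categories supported")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("table has zero total count")

    @property
    def n(self) -> float:
        return float(self.counts.sum())


def crosstab(
    records: Iterable[TwinPairRecord],
    group: str | Sequence[str] | Callable[[TwinPairRecord], bool],
    collapse: str | dict[int, Optional[int]] = "three",
    proband_sex: Optional[str] = None,
) -> PairTable:
    """Cross-tabulate co-twin statuses for a zygosity selection.

    ``group`` selects pairs by zygosity-group name(s) or a predicate.
    ``collapse`` is a named rule from :data:`COLLAPSE_RULES` or an
    explicit status map; a pair is dropped when either twin maps to
    ``None``.  For opposite-sex groups, ``proband_sex`` ("F" or "M")
    orients the table so rows are the proband of that sex (pairs stored
    with the other ordering are transposed in).
    """
    rule = COLLAPSE_RULES[collapse] if isinstance(collapse, str) else collapse
    if callable(group):
        pred = group
        label = "custom"
    else:
        names = (group,) if isinstance(group, str) else tuple(group)
        expanded: list[str] = []
        for nm in names:
            if nm == "MZ":
                expanded += ["MZ-FF", "MZ-MM"]
            elif nm == "DZ":
                expanded += ["DZ-FF", "DZ-MM", "DZ-FM", "DZ-MF"]
            elif nm == "DZss":
                expanded += ["DZ-FF", "DZ-MM"]
            elif nm == "DZos":
                expanded += ["DZ-FM", "DZ-MF"]
            else:
                expanded.append(nm)
        pred = lambda rec: rec.zygosity_group in expanded  # noqa: E731
        label = "+".join(names)

    k = len(set(v for v in rule.values() if v is not None))
    counts = np.zeros((k, k), dtype=float)
    n_selected = 0
    same_sex = True
    for rec in records:
        if not pred(rec):
            continue
        s1, s2 = rule[rec.status1], rule[rec.status2]
        if s1 is None or s2 is None:
            continue
        if proband_sex is not None and not rec.same_sex and rec.sex1 != proband_sex:
            s1, s2 = s2, s1
        counts[s1, s2] += 1
        n_selected += 1
        same_sex = same_sex and rec.same_sex
    if n_selected == 0:
        raise ValueError(f"no pairs selected for group {label!r}")
    labels = tuple(f"cat{i}" for i in range(k))
    return PairTable(counts=counts, category_labels=labels, zygosity_group=label, same_sex=same_sex)


def symmetrize(table: PairTable) -> PairTable:
    """Average over the choice of proband: (counts + counts.T) / 2.

    Only meaningful for same-sex groups, where twin ordering is
    arbitrary; the pair total is preserved and half-counts may appear.
    """
    if not table.same_sex:
        raise ValueError("symmetrize is only valid for same-sex groups; "
                         "proband direction is meaningful for opposite-sex pairs")
    return PairTable(
        counts=(table.counts + table.counts.T) / 2.0,
        category_labels=table.category_labels,
        zygosity_group=table.zygosity_group,
        same_sex=table.same_sex,
    )


@dataclass(frozen=True)
class RelativeRiskEstimate:
    """RR of a co-twin outcome for an affected vs non-depressed proband."""

    proband_condition: tuple[int, ...]
    cotwin_outcome: tuple[int, ...]
    rr: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_exposed: float
    n_reference: float
    estimable: bool = True
    reason: Optional[str] = None

    def format(self) -> str:
        if not self.estimable:
            return "—"
        return f"{self.rr:.2f} ({self.ci_low:.2f}–{self.ci_high:.2f})"


def relative_risk(
    table: PairTable,
    proband_condition: int | Sequence[int],
    cotwin_outcome: int | Sequence[int],
    reference: int = 0,
    z: float = 1.959963984540054,
) -> RelativeRiskEstimate:
    """Relative risk of ``cotwin_outcome`` for probands in ``proband_condition``.

    Both arguments may be category unions (e.g. minor-or-major); member
    cells are summed before risks are formed.  The reference probands are
    the non-depressed row.  The 95% CI is the Katz log-normal interval
    exp(log RR ± z * sqrt(1/x1 - 1/n1 + 1/x0 - 1/n0)).  A zero exposed
    margin, zero reference risk or zero exposed-outcome count yields a
    non-estimable result with a reason code rather than an exception.
    """
    cond = (proband_condition,) if isinstance(proband_condition, int) else tuple(proband_condition)
    outc = (cotwin_outcome,) if isinstance(cotwin_outcome, int) else tuple(cotwin_outcome)
    if reference in cond:
        raise ValueError("proband condition must exclude the reference (non-depressed) category")

    c = table.counts
    n1 = float(c[list(cond), :].sum())
    x1 = float(c[np.ix_(list(cond), list(outc))].sum())
    n0 = float(c[reference, :].sum())
    x0 = float(c[reference, list(outc)].sum())

    def not_estimable(reason: str) -> RelativeRiskEstimate:
        return RelativeRiskEstimate(cond, outc, None, None, None, n1, n0,
                                    estimable=False, reason=reason)

    if n1 == 0:
        return not_estimable("no probands in condition")
    if n0 == 0:
        return not_estimable("no reference probands")
    if x0 == 0:
        return not_estimable("zero reference risk")
    if x1 == 0:
        return not_estimable("zero outcome count among exposed")

    rr = (x1 / n1) / (x0 / n0)
    se = np.sqrt(max(0.0, 1.0 / x1 - 1.0 / n1 + 1.0 / x0 - 1.0 / n0))
    lo, hi = np.exp(np.log(rr) - z * se), np.exp(np.log(rr) + z * se)
    return RelativeRiskEstimate(cond, outc, float(rr), float(lo), float(hi), n1, n0)
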