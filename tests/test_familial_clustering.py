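"""Relative-risk machinery: cross-tabulation, symmetrization, Katz CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinliab.familial_clustering import (
    PairTable,
    crosstab,
    relative_risk,
    symmetrize,
)
from twinliab.synthetic_cohort import (
    SimulationParams,
    TwinPairRecord,
    preset_params,
    simulate_cohort,
    thresholds_from_prevalences,
)


def _pairs(statuses, group="MZ-FF"):
    return [
        TwinPairRecord(pair_id=str(i), zygosity_group=group, age=60.0,
                       status1=s1, status2=s2)
        for i, (s1, s2) in enumerate(statuses)
    ]


def test_crosstab_counts_directly():
    recs = _pairs([(0, 0), (1, 2), (2, 1)])
    tab = crosstab(recs, "MZ", "three")
    expected = np.zeros((3, 3))
    expected[0, 0] = expected[1, 2] = expected[2, 1] = 1
    assert np.array_equal(tab.counts, expected)
    two = crosstab(recs, "MZ", "two")
    assert two.counts[0, 0] == 1 and two.counts[1, 1] == 2 and two.counts.sum() == 3


def test_crosstab_empty_selection_is_an_error():
    recs = _pairs([(0, 0)])
    with pytest.raises(ValueError):
        crosstab(recs, "DZ", "three")


def test_crosstab_conserves_pairs_on_aged_preset(aged_cohort):
    total = sum(
        crosstab(aged_cohort, g, "three").n
        for g in ("MZ-FF", "MZ-MM", "DZ-FF", "DZ-MM", "DZ-FM", "DZ-MF")
    )
    assert total == 1220


def test_crosstab_orients_opposite_sex_probands(aged_cohort):
    fm = crosstab(aged_cohort, "DZos", "three", proband_sex="F")
    mf = crosstab(aged_cohort, "DZos", "three", proband_sex="M")
    assert fm.n == mf.n == 241
    assert np.array_equal(fm.counts, mf.counts.T)


def test_symmetrize_examples():
    tab = PairTable(np.array([[0.0, 2.0], [4.0, 0.0]]), ("a", "b"), "MZ")
    sym = symmetrize(tab)
    assert np.array_equal(sym.counts, [[0, 3], [3, 0]])
    assert np.array_equal(symmetrize(sym).counts, sym.counts)  # idempotent


def test_symmetrize_rejects_opposite_sex_tables():
    tab = PairTable(np.ones((2, 2)), ("a", "b"), "DZos", same_sex=False)
    with pytest.raises(ValueError):
        symmetrize(tab)


@settings(max_examples=200, deadline=None)
@given(st.lists(st.integers(0, 50), min_size=9, max_size=9))
def test_symmetrize_preserves_total_and_is_symmetric(cells):
    counts = np.array(cells, dtype=float).reshape(3, 3)
    if counts.sum() == 0:
        counts[0, 0] = 1
    tab = PairTable(counts, ("a", "b", "c"), "MZ")
    sym = symmetrize(tab)
    assert sym.counts.sum() == pytest.approx(tab.counts.sum())
    assert np.allclose(sym.counts, sym.counts.T)


def test_relative_risk_equal_risks_is_one():
    tab = PairTable(np.array([[60.0, 20.0], [30.0, 10.0]]), ("a", "b"), "MZ")
    rr = relative_risk(tab, 1, 1)
    assert rr.rr == pytest.approx(1.0)


def test_relative_risk_hand_computed_two_by_two():
    # proband-depressed row: 10/30 affected; reference row: 20/70
    tab = PairTable(np.array([[50.0, 20.0], [20.0, 10.0]]), ("nd", "dep"), "MZ")
    rr = relative_risk(tab, 1, 1)
    assert rr.rr == pytest.approx((10 / 30) / (20 / 70))
    se = np.sqrt(1 / 10 - 1 / 30 + 1 / 20 - 1 / 70)
    assert rr.ci_low == pytest.approx(rr.rr * np.exp(-1.96 * se), rel=1e-3)
    assert rr.ci_high == pytest.approx(rr.rr * np.exp(1.96 * se), rel=1e-3)


def test_katz_interval_agrees_with_parametric_bootstrap(rng):
    # independent route: resample the two rows at their observed risks and
    # take percentile bounds of the log-RR distribution
    x1, n1, x0, n0 = 10, 30, 20, 70
    tab = PairTable(np.array([[n0 - x0, x0], [n1 - x1, x1]], dtype=float), ("nd", "dep"), "MZ")
    est = relative_risk(tab, 1, 1)
    boots = []
    for _ in range(4000):
        b1 = rng.binomial(n1, x1 / n1)
        b0 = rng.binomial(n0, x0 / n0)
        if 0 < b1 and 0 < b0:
            boots.append((b1 / n1) / (b0 / n0))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    assert est.ci_low == pytest.approx(lo, abs=0.2)
    assert est.ci_high == pytest.approx(hi, abs=0.75)


def test_union_conditions_sum_member_cells():
    counts = np.array([[40.0, 5.0, 5.0], [10.0, 6.0, 4.0], [5.0, 3.0, 2.0]])
    tab = PairTable(counts, ("nd", "mi", "ma"), "MZ")
    rr_union = relative_risk(tab, (1, 2), (1, 2))
    risk_exposed = (6 + 4 + 3 + 2) / 30
    risk_ref = (5 + 5) / 50
    assert rr_union.rr == pytest.approx(risk_exposed / risk_ref)


def test_non_estimable_results_carry_reasons():
    counts = np.array([[50.0, 0.0], [10.0, 0.0]])
    est = relative_risk(PairTable(counts, ("a", "b"), "MZ"), 1, 1)
    assert not est.estimable and est.reason == "zero reference risk"
    assert est.format() == "—"
    counts = np.array([[40.0, 10.0], [5.0, 0.0]])
    est = relative_risk(PairTable(counts, ("a", "b"), "MZ"), 1, 1)
    assert not est.estimable and "exposed" in est.reason


def test_reference_category_cannot_be_the_condition():
    tab = PairTable(np.ones((2, 2)), ("a", "b"), "MZ")
    with pytest.raises(ValueError):
        relative_risk(tab, 0, 1)


def test_mz_exceeds_dz_relative_risk_under_additive_genetics():
    thr = thresholds_from_prevalences(0.0898, 0.0205)
    mz_rrs, dz_rrs = [], []
    for seed in range(15):
        p = SimulationParams(a2=0.47, e2=0.53, thresholds=thr,
                             n_pairs_by_group={"MZ-FF": 2000, "DZ-FF": 2000}, seed=seed)
        recs = simulate_cohort(p)
        for zyg, acc in (("MZ", mz_rrs), ("DZ", dz_rrs)):
            est = relative_risk(symmetrize(crosstab(recs, zyg, "two")), 1, 1)
            if est.estimable:
                acc.append(est.rr)
    assert np.mean(mz_rrs) > np.mean(dz_rrs)


def test_katz_interval_coverage_is_nominal(rng):
    # 600 simulated 2x2 tables at fixed true risks; true RR = 2.5
    p1, p0, n1, n0 = 0.25, 0.10, 120, 300
    true_rr = p1 / p0
    hits = trials = 0
    for _ in range(600):
        x1 = rng.binomial(n1, p1)
        x0 = rng.binomial(n0, p0)
        counts = np.array([[n0 - x0, x0], [n1 - x1, x1]], dtype=float)
        est = relative_risk(PairTable(counts, ("a", "b"), "MZ"), 1, 1)
        if est.estimable:
            trials += 1
            hits += est.ci_low <= true_rr <= est.ci_high
    assert trials > 550
    assert 0.93 <= hits / trials <= 0.97
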