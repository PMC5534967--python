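"""ACE/ADE ordinal twin model: likelihood, fitting, LRT, AIC, profile CIs."""

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.stats import norm

from twinliab.synthetic_cohort import (
    SimulationParams,
    TwinPairRecord,
    simulate_cohort,
    thresholds_from_prevalences,
)
from twinliab.variance_components import (
    BiometricFit,
    ModelSpec,
    ParamSet,
    aic,
    fit_model,
    likelihood_ratio_test,
    pair_loglik,
    profile_ci,
)

THR = thresholds_from_prevalences(0.0898, 0.0205)


def _ae_cohort(a2=0.4, n=5000, seed=7):
    p = SimulationParams(a2=a2, e2=1 - a2, thresholds=THR,
                         n_pairs_by_group={"MZ-FF": n, "DZ-FF": n}, seed=seed)
    return simulate_cohort(p)


def test_model_spec_validation():
    for ok in ("ACE", "ADE", "AE", "CE", "E"):
        ModelSpec(ok)
    with pytest.raises(ValueError):
        ModelSpec("ACDE")
    with pytest.raises(ValueError):
        ModelSpec("AD")
    assert ModelSpec("ACE").n_free_params == 2 + 2  # u_a, u_c + two thresholds
    assert ModelSpec("E", covariates=("age", "sex")).n_free_params == 0 + 2 + 2
    assert ModelSpec("AE").is_nested_in(ModelSpec("ADE"))
    assert not ModelSpec("CE").is_nested_in(ModelSpec("ADE"))


def test_pair_loglik_factorises_under_e_model():
    params = ParamSet(a2=0.0, c2=0.0, d2=0.0, thresholds=THR)
    rec = TwinPairRecord("x", "MZ-FF", 60.0, 1, 2)
    cum = np.concatenate(([0.0], norm.cdf(THR), [1.0]))
    marg = np.diff(cum)
    expected = np.log(marg[1]) + np.log(marg[2])
    assert pair_loglik(rec, ModelSpec("E"), params) == pytest.approx(expected, abs=1e-12)


def test_pair_loglik_discordant_mass_vanishes_at_full_heritability():
    rec = TwinPairRecord("x", "MZ-FF", 60.0, 0, 2)
    lls = []
    for a2 in (0.9, 0.99, 0.999):
        params = ParamSet(a2=a2, c2=0.0, d2=0.0, thresholds=THR)
        lls.append(pair_loglik(rec, ModelSpec("AE"), params))
    assert lls[0] > lls[1] > lls[2]
    assert lls[2] < -8


def test_pair_loglik_agrees_with_dense_double_integration(rng):
    for _ in range(10):
        a2 = rng.uniform(0.1, 0.8)
        c2 = rng.uniform(0.0, 1 - a2 - 0.05)
        t1 = rng.uniform(-0.5, 0.5)
        t2 = t1 + rng.uniform(0.4, 1.2)
        beta_age, beta_sex = rng.normal(0, 0.02), rng.normal(0, 0.2)
        params = ParamSet(a2=a2, c2=c2, d2=0.0, thresholds=(t1, t2),
                          beta_age=beta_age, beta_sex=beta_sex, age_ref=60.0)
        s1, s2 = int(rng.integers(0, 3)), int(rng.integers(0, 3))
        group = "DZ-FM" if rng.random() < 0.5 else "MZ-MM"
        rec = TwinPairRecord("x", group, float(rng.uniform(50, 80)), s1, s2)
        rho = params.r_mz if rec.is_mz else params.r_dz
        det = 1 - rho**2

        def bounds(status, sex):
            shift = beta_age * (rec.age - 60.0) + beta_sex * (sex == "M")
            ts = np.array([t1, t2]) + shift
            lo = -8.0 if status == 0 else ts[status - 1]
            hi = 8.0 if status == 2 else ts[status]
            return lo, hi

        lo1, hi1 = bounds(s1, rec.sex1)
        lo2, hi2 = bounds(s2, rec.sex2)
        ref, _ = dblquad(
            lambda y, x: np.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * det))
            / (2 * np.pi * np.sqrt(det)),
            lo1, hi1, lo2, hi2, epsabs=1e-12, epsrel=1e-12,
        )
        got = pair_loglik(rec, ModelSpec("ACE"), params)
        assert got == pytest.approx(np.log(ref), abs=1e-8)


def test_e_model_estimates_are_exact():
    recs = _ae_cohort(n=200)
    fit = fit_model(recs, ModelSpec("E"))
    assert fit.estimates == {"a2": 0.0, "c2": 0.0, "d2": 0.0, "e2": 1.0}


def test_ae_parameter_recovery():
    recs = _ae_cohort(a2=0.4, n=5000, seed=11)
    fit = fit_model(recs, ModelSpec("AE"))
    assert fit.estimates["a2"] == pytest.approx(0.4, abs=0.05)
    assert fit.estimates["e2"] == pytest.approx(1 - fit.estimates["a2"], abs=1e-8)


def test_equal_twin_correlations_push_a2_to_zero():
    # r_MZ = r_DZ can only arise from common environment under ACE
    p = SimulationParams(a2=0.0, c2=0.3, e2=0.7, thresholds=THR,
                         n_pairs_by_group={"MZ-FF": 4000, "DZ-FF": 4000}, seed=13)
    recs = simulate_cohort(p)
    fit = fit_model(recs, ModelSpec("ACE"))
    assert fit.estimates["a2"] < 0.08
    assert fit.estimates["c2"] == pytest.approx(0.3, abs=0.06)


def test_nested_minus2ll_monotone_and_lrt_grid(aged_cohort):
    fits = {m: fit_model(aged_cohort, ModelSpec(m)) for m in ("ACE", "AE", "CE", "E")}
    full = fits["ACE"]
    for m in ("AE", "CE", "E"):
        assert fits[m].minus2LL >= full.minus2LL - 1e-6
        res = likelihood_ratio_test(full, fits[m])
        assert res.chi2 >= 0 and 0 <= res.p <= 1
        assert res.df == (2 if m == "E" else 1)


def test_lrt_closed_form_worked_examples():
    # chi2 tail probabilities recomputable from published -2LL pairs
    full = BiometricFit.from_minus2ll("ACE", 1446.58)
    nested = BiometricFit.from_minus2ll("E", 1460.62)
    res = likelihood_ratio_test(full, nested)
    assert res.df == 2
    assert res.p == pytest.approx(8.9e-4, rel=0.01)
    res = likelihood_ratio_test(
        BiometricFit.from_minus2ll("ACE", 475.73), BiometricFit.from_minus2ll("CE", 476.73)
    )
    assert res.df == 1
    assert res.p == pytest.approx(0.32, abs=0.005)
    same = likelihood_ratio_test(
        BiometricFit.from_minus2ll("ACE", 100.0), BiometricFit.from_minus2ll("AE", 100.0)
    )
    assert same.chi2 == 0.0 and same.p == 1.0


def test_lrt_rejects_non_nested_pairs():
    with pytest.raises(ValueError):
        likelihood_ratio_test(
            BiometricFit.from_minus2ll("ADE", 10.0), BiometricFit.from_minus2ll("CE", 12.0)
        )


def test_aic_penalises_parameters():
    a = BiometricFit.from_minus2ll("ACE", 500.0)
    b = BiometricFit.from_minus2ll("AE", 500.0)
    assert aic(a) - aic(b) == pytest.approx(2.0)


def test_aic_prefers_ae_when_c2_hits_zero(aged_cohort):
    ace = fit_model(aged_cohort, ModelSpec("ACE"))
    ae = fit_model(aged_cohort, ModelSpec("AE"))
    if ace.estimates["c2"] < 1e-6:
        assert ae.minus2LL == pytest.approx(ace.minus2LL, abs=1e-4)
        assert aic(ae) < aic(ace)


def test_profile_ci_contains_estimate_and_clamps_at_zero():
    recs = _ae_cohort(a2=0.4, n=2000, seed=17)
    fit = fit_model(recs, ModelSpec("AE"))
    lo, hi = profile_ci(recs, fit, "a2")
    assert 0.0 <= lo <= fit.estimates["a2"] <= hi <= 1.0
    # a component estimated on the boundary gets a lower bound of exactly 0
    ace = fit_model(recs, ModelSpec("ACE"))
    if ace.estimates["c2"] < 1e-6:
        lo_c, hi_c = profile_ci(recs, ace, "c2")
        assert lo_c == 0.0
        assert hi_c > 0.0


def test_fit_invariant_to_twin_label_swap():
    recs = _ae_cohort(a2=0.4, n=800, seed=19)
    swapped = [
        TwinPairRecord(r.pair_id, r.zygosity_group, r.age, r.status2, r.status1)
        for r in recs
    ]
    f1 = fit_model(recs, ModelSpec("AE"))
    f2 = fit_model(swapped, ModelSpec("AE"))
    assert f1.minus2LL == pytest.approx(f2.minus2LL, abs=1e-6)
    assert f1.estimates["a2"] == pytest.approx(f2.estimates["a2"], abs=1e-5)


def test_e_model_matches_closed_form_marginal_likelihood():
    # with r = 0 and saturated thresholds the ML solution is the empirical
    # category frequencies; -2LL has a closed form
    recs = _ae_cohort(a2=0.3, n=1500, seed=23)
    fit = fit_model(recs, ModelSpec("E"))
    statuses = np.array([[r.status1, r.status2] for r in recs]).ravel()
    counts = np.bincount(statuses, minlength=3)
    phat = counts / counts.sum()
    expected = -2 * np.sum(counts * np.log(phat))
    assert fit.minus2LL == pytest.approx(expected, abs=1e-4)


def test_sex_covariate_recovers_threshold_shift():
    p = SimulationParams(
        a2=0.4, e2=0.6, thresholds=THR, beta_sex=0.3,
        n_pairs_by_group={"MZ-FF": 3000, "MZ-MM": 3000, "DZ-FF": 3000, "DZ-MM": 3000},
        seed=29,
    )
    recs = simulate_cohort(p)
    fit = fit_model(recs, ModelSpec("AE", covariates=("sex",)))
    # single-replicate tolerances at roughly 3 Monte-Carlo SDs
    assert fit.params.beta_sex == pytest.approx(0.3, abs=0.1)
    assert fit.estimates["a2"] == pytest.approx(0.4, abs=0.1)


def test_exclusion_modes_differ_only_in_singletons():
    recs = _ae_cohort(a2=0.4, n=400, seed=31)
    spec = ModelSpec("AE", n_categories=2)
    pair_drop = fit_model(recs, spec, collapse="major-only", exclusion="pair")
    ind_drop = fit_model(recs, spec, collapse="major-only", exclusion="individual")
    # the individual-drop likelihood includes extra marginal terms
    assert ind_drop.minus2LL > pair_drop.minus2LL
    assert abs(ind_drop.estimates["a2"] - pair_drop.estimates["a2"]) < 0.2
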