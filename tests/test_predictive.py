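"""QIC, marginal R^2, multivariable fits and forward selection."""

import math
import types
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from neomort.cohort import build_cohort
from neomort.predictive import (
    ForwardQICSelector,
    fit_multivariable,
    forward_select,
    marginal_r2,
    qic,
)
from neomort.simulate import RiskModel, generate_registry, small_config
from neomort.variables import add_derived, death_indicator


def test_intercept_only_fit_matches_crude_risk(small_cohort):
    result, summary = fit_multivariable(small_cohort, [])
    y = death_indicator(small_cohort.data).dropna()
    assert math.exp(result.params[0]) == pytest.approx(y.mean(), abs=1e-6)
    assert summary.marginal_r2 == pytest.approx(0.0, abs=1e-12)


def test_marginal_r2_is_one_for_perfect_fit():
    y = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
    stub = types.SimpleNamespace(
        model=types.SimpleNamespace(endog=y), fittedvalues=y.copy()
    )
    assert marginal_r2(stub) == 1.0


def test_marginal_r2_undefined_for_constant_outcome():
    y = np.zeros(10)
    stub = types.SimpleNamespace(
        model=types.SimpleNamespace(endog=y), fittedvalues=y + 0.1
    )
    with pytest.warns(UserWarning, match="zero variance"):
        assert np.isnan(marginal_r2(stub))


def test_qic_deterministic_across_refits(small_cohort):
    _, s1 = fit_multivariable(small_cohort, ["birth_weight_band"])
    _, s2 = fit_multivariable(small_cohort, ["birth_weight_band"])
    assert s1.qic == s2.qic


def test_qic_within_2pct_of_classical_criterion_on_independent_data():
    """Independence limit: QIC ~ -2 loglik + 2p from an oracle GLM fit."""
    rng = np.random.default_rng(3)
    n = 500
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = (rng.random(n) < np.exp(-3.0 + 0.5 * X[:, 1])).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gee = sm.GEE(
            y,
            X,
            groups=np.arange(n),
            family=sm.families.Poisson(),
            cov_struct=sm.cov_struct.Independence(),
        ).fit()
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    classical = -2.0 * glm.llf + 2 * X.shape[1]
    assert qic(gee) == pytest.approx(classical, rel=0.02)


def test_quasi_likelihood_gap_matches_statsmodels_cross_check(small_cohort):
    """Quasi-likelihood gaps between nested models agree with the library's
    numerically integrated quasi-likelihood.

    The conventions differ by a model-independent constant (deviance-form vs
    direct form), so differences are the comparable quantity.
    """
    from neomort.predictive import quasi_loglik

    r0, _ = fit_multivariable(small_cohort, ["education"])
    r1, _ = fit_multivariable(small_cohort, ["education", "anc_visits_category"])

    def my_ql(r):
        return quasi_loglik(
            np.asarray(r.model.endog), np.asarray(r.fittedvalues), r.model.family
        )

    def sm_ql(r):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return r.model.qic(r.params, 1.0, r.cov_params())[0]

    assert (my_ql(r1) - my_ql(r0)) == pytest.approx(sm_ql(r1) - sm_ql(r0), abs=0.05)


def test_adding_noise_covariate_usually_raises_qic():
    """A pure-noise covariate should be penalised in >=80% of replicates."""
    rm = RiskModel(
        intercept=math.log(0.01),
        categorical_log_rr={},
        ga_log_rr_per_week_decrease=0.25,
    )
    cfg = small_config(
        n_clusters=20, deliveries=(300, 320), covariate_missing_rate=0.0, risk_model=rm
    )
    increased = 0
    reps = 100
    for rep in range(reps):
        maternal, infants, _, _ = generate_registry(cfg, seed=5000 + rep)
        cohort = build_cohort(maternal, infants)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, with_signal = fit_multivariable(cohort, ["ga_delivery_weeks"])
            _, with_noise = fit_multivariable(
                cohort, ["ga_delivery_weeks", "education"]
            )
        increased += with_noise.qic > with_signal.qic
    assert increased / reps >= 0.80


def test_forward_select_single_strong_candidate(small_cohort):
    path = forward_select(small_cohort, ["birth_weight_band"])
    assert path.selected == ["birth_weight_band"]
    assert len([s for s in path.steps if s.chosen]) == 1


def test_selection_path_qic_monotone_and_order_insensitive(small_cohort):
    cands = ["birth_weight_band", "education", "anc_visits_category"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path = forward_select(small_cohort, cands)
        path_perm = forward_select(small_cohort, cands[::-1])
    qics = [path.steps[0].qic_before] + [
        s.qic_after for s in path.steps if s.chosen
    ]
    assert all(b <= a + 1e-9 for a, b in zip(qics, qics[1:]))
    assert set(path.selected) == set(path_perm.selected)


def test_forward_select_true_predictor_found_and_nulls_mostly_rejected():
    """Birth weight is always found; all-null runs mostly stay intercept-only."""
    rm = RiskModel(
        categorical_log_rr={
            "birth_weight_band": {
                "<1000": math.log(25.6),
                "1000-1499": math.log(19.8),
                "1500-2499": math.log(3.1),
            }
        }
    )
    cfg = small_config(
        n_clusters=20, deliveries=(120, 140), covariate_missing_rate=0.0, risk_model=rm
    )
    found_first = 0
    null_empty = 0
    reps = 40
    for rep in range(reps):
        maternal, infants, _, _ = generate_registry(cfg, seed=6000 + rep)
        cohort = build_cohort(maternal, infants)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path = forward_select(
                cohort, ["birth_weight_band", "education", "age_category"]
            )
            null_path = forward_select(cohort, ["education", "age_category"])
        found_first += bool(path.selected and path.selected[0] == "birth_weight_band")
        null_empty += null_path.selected == []
    assert found_first / reps >= 0.90
    assert null_empty / reps > 0.5


def test_multivariable_recovers_generating_effects():
    cfg = small_config(n_clusters=20, deliveries=(340, 360), covariate_missing_rate=0.0)
    maternal, infants, _, truth = generate_registry(cfg, seed=23)
    cohort = build_cohort(maternal, infants)
    _, summary = fit_multivariable(cohort, ["birth_weight_band", "anc_visits_category"])
    terms = {e.label: e for e in summary.estimates}
    gen = truth.risk_model.categorical_log_rr["birth_weight_band"]
    est = terms["birth_weight_band[1500-2499]"]
    assert est.ci_low <= math.exp(gen["1500-2499"]) <= est.ci_high


def test_adjusted_rr_ordering_and_r2_band_at_strong_effect_sizes():
    """Strong univariate-scale birth-weight effects: monotone adjusted RRs
    and a marginal R^2 in the plausible 0.1-0.35 band (regression snapshot)."""
    rm = RiskModel(
        intercept=math.log(0.0113),
        categorical_log_rr={
            "birth_weight_band": {
                "<1000": math.log(82.6),
                "1000-1499": math.log(41.1),
                "1500-2499": math.log(3.68),
            }
        },
    )
    cfg = small_config(
        n_clusters=20,
        deliveries=(300, 320),
        years=(2014, 2015),
        covariate_missing_rate=0.0,
        risk_model=rm,
    )
    maternal, infants, _, _ = generate_registry(cfg, seed=31)
    cohort = build_cohort(maternal, infants)
    _, summary = fit_multivariable(cohort, ["birth_weight_band"])
    rr = {e.label.split("[")[1].rstrip("]"): e.rr for e in summary.estimates}
    assert rr["<1000"] > rr["1000-1499"] > rr["1500-2499"] > 1.0
    assert 0.1 <= summary.marginal_r2 <= 0.35


def test_collinear_term_dropped_with_warning():
    rng = np.random.default_rng(1)
    n = 400
    preterm = rng.random(n) < 0.2
    df = pd.DataFrame(
        {
            "cluster_id": np.repeat([f"c{k}" for k in range(8)], 50),
            "alive_at_28d": rng.random(n) > 0.05,
            "ga_delivery_weeks": np.where(preterm, 33.0, 39.0),
            "birth_weight_g": 3000.0,
            "multiple_gestation": preterm,  # aliased with preterm indicator
        }
    )
    with pytest.warns(UserWarning, match="aliased"):
        _, summary = fit_multivariable(df, ["preterm", "multiple_gestation"])
    assert [e.label for e in summary.estimates] == ["preterm"]


def test_selector_follows_estimator_conventions(small_cohort):
    from sklearn.base import clone

    sel = ForwardQICSelector(candidates=["birth_weight_band"], max_steps=1)
    clone(sel)
    sel.fit(small_cohort)
    assert sel.selected_ == ["birth_weight_band"]
    assert sel.summary_.qic == sel.path_.final_summary.qic
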