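"""Crude and cluster-robust relative-risk estimation."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from neomort.cohort import build_cohort
from neomort.risk import (
    ClusterRelativeRisk,
    RiskModelError,
    TwoByTwo,
    cluster_rr,
    continuous_rr,
    crude_rr,
    two_by_two,
)
from neomort.simulate import RiskModel, generate_registry, small_config


@pytest.mark.parametrize(
    "table, expected_rr",
    [
        (TwoByTwo(364, 3235, 394, 27708), 7.91),  # preterm vs term
        (TwoByTwo(75, 572, 683, 30371), 5.83),  # multiple vs singleton
        (TwoByTwo(69, 2106, 360, 16921), 1.54),  # parity >=3 vs 1-2
        (TwoByTwo(329, 11914, 360, 16921), 1.30),  # parity 0 vs 1-2
    ],
)
def test_crude_rr_reproduces_printed_estimates(table, expected_rr):
    assert round(crude_rr(table).rr, 2) == expected_rr


def test_symmetric_table_gives_unity_with_ci_spanning_one():
    est = crude_rr(TwoByTwo(10, 100, 10, 100))
    assert est.rr == 1.0
    assert est.ci_low < 1.0 < est.ci_high
    assert est.p_value == 1.0


def test_reference_level_against_itself_is_exactly_one():
    est = crude_rr(TwoByTwo(360, 16921, 360, 16921))
    assert est.rr == 1.0


def test_cell_scaling_preserves_rr_and_narrows_ci():
    base = crude_rr(TwoByTwo(20, 200, 30, 600))
    scaled = crude_rr(TwoByTwo(200, 2000, 300, 6000))
    assert math.isclose(base.rr, scaled.rr)
    assert (scaled.ci_high - scaled.ci_low) < (base.ci_high - base.ci_low)


def test_zero_cells_flagged_unbounded_not_raised():
    est = crude_rr(TwoByTwo(0, 50, 5, 50))
    assert est.rr == 0.0 and est.unbounded_ci
    est = crude_rr(TwoByTwo(5, 50, 0, 50))
    assert np.isinf(est.rr) and est.unbounded_ci
    with pytest.raises(ValueError):
        crude_rr(TwoByTwo(0, 0, 5, 50))


def test_wald_ci_agrees_with_nonparametric_bootstrap():
    """10,000-rep bootstrap of the multiple-gestation 2x2 as an oracle."""
    a, n1, c, n0 = 75, 572, 683, 30371
    rng = np.random.default_rng(2024)
    boot_a = rng.binomial(n1, a / n1, 10_000)
    boot_c = rng.binomial(n0, c / n0, 10_000)
    ok = (boot_a > 0) & (boot_c > 0)
    log_rr = np.log((boot_a[ok] / n1) / (boot_c[ok] / n0))
    lo, hi = np.quantile(log_rr, [0.025, 0.975])
    est = crude_rr(TwoByTwo(a, n1, c, n0))
    assert round(est.rr, 2) == 5.83
    assert math.log(est.ci_low) == pytest.approx(lo, abs=0.05)
    assert math.log(est.ci_high) == pytest.approx(hi, abs=0.05)


def _degenerate_cluster_frame(seed=42, n=800):
    rng = np.random.default_rng(seed)
    x = rng.random(n) < 0.3
    y = rng.random(n) < 0.05 * np.where(x, 3.0, 1.0)
    return pd.DataFrame(
        {
            "cluster_id": [f"c{i}" for i in range(n)],  # every cluster size 1
            "alive_at_28d": ~y,
            "multiple_gestation": x,
            "birth_weight_g": np.nan,
            "ga_delivery_weeks": np.nan,
        }
    ), x, y


def test_degenerate_clusters_match_nonclustered_ml():
    df, x, y = _degenerate_cluster_frame()
    fit = ClusterRelativeRisk(exposure="multiple_gestation").fit(df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(
            y.astype(float),
            np.column_stack([np.ones(len(df)), x.astype(float)]),
            family=sm.families.Binomial(link=sm.families.links.Log()),
        ).fit()
    assert np.allclose(fit.params_, glm.params, rtol=1e-6)


def test_single_cluster_raises_informative_error():
    df, _, _ = _degenerate_cluster_frame()
    df["cluster_id"] = "only"
    with pytest.raises(RiskModelError, match="at least 2 clusters"):
        ClusterRelativeRisk(exposure="multiple_gestation").fit(df)


def test_no_cluster_variance_crude_and_gee_agree():
    """With zero cluster effect the GEE point estimates match the closed form."""
    cfg = small_config(
        n_clusters=20,
        deliveries=(200, 220),
        covariate_missing_rate=0.0,
        risk_model=RiskModel(cluster_sd=0.0),
    )
    maternal, infants, _, _ = generate_registry(cfg, seed=5)
    cohort = build_cohort(maternal, infants)
    ests, _ = cluster_rr(cohort, "birth_weight_band")
    for est in ests:
        level = est.label.split("[")[1].rstrip("]")
        crude = crude_rr(two_by_two(cohort, "birth_weight_band", level, ">=2500"))
        if crude.unbounded_ci or est.rr == 0.0:
            continue  # empty band at this scale
        assert est.rr == pytest.approx(crude.rr, rel=0.01)


def test_null_exposure_ci_covers_one_at_nominal_rate():
    """Reduced null simulation: cluster-robust CI covers 1 around 95%."""
    rng = np.random.default_rng(77)
    covered = 0
    reps = 60
    for _ in range(reps):
        g = np.repeat([f"c{k}" for k in range(20)], 250)
        u = np.repeat(rng.normal(0, 0.25, 20), 250)
        x = rng.random(5000) < 0.1  # no effect on outcome
        y = rng.random(5000) < np.minimum(0.02 * np.exp(u), 1)
        df = pd.DataFrame(
            {
                "cluster_id": g,
                "alive_at_28d": ~y,
                "multiple_gestation": x,
                "birth_weight_g": np.nan,
                "ga_delivery_weeks": np.nan,
            }
        )
        est = ClusterRelativeRisk(exposure="multiple_gestation").fit(df).estimates_[0]
        covered += est.ci_low <= 1.0 <= est.ci_high
    assert covered / reps >= 0.86  # 95% nominal minus Monte-Carlo slack


def test_continuous_rr_recovers_generating_slope():
    rm = RiskModel(
        intercept=math.log(0.004),
        categorical_log_rr={},
        ga_log_rr_per_week_decrease=0.25,
    )
    cfg = small_config(
        n_clusters=20, deliveries=(300, 320), covariate_missing_rate=0.0, risk_model=rm
    )
    maternal, infants, _, _ = generate_registry(cfg, seed=17)
    cohort = build_cohort(maternal, infants)
    est = continuous_rr(cohort, "ga_delivery_weeks")
    assert est.ci_low <= math.exp(0.25) <= est.ci_high
    assert est.rr == pytest.approx(math.exp(0.25), rel=0.15)


def test_continuous_rr_sign_symmetry(small_cohort):
    dec = continuous_rr(small_cohort, "ga_delivery_weeks", per_unit_decrease=True)
    negated = small_cohort.data.copy()
    negated["ga_delivery_weeks"] = -pd.to_numeric(
        negated["ga_delivery_weeks"], errors="coerce"
    )
    inc_on_negated = continuous_rr(negated, "ga_delivery_weeks", per_unit_decrease=False)
    assert inc_on_negated.rr == pytest.approx(dec.rr, rel=1e-9)


def test_constant_variable_hard_error(small_cohort):
    df = small_cohort.data.copy()
    df["ga_delivery_weeks"] = 39.0
    with pytest.raises(RiskModelError, match="constant"):
        continuous_rr(df, "ga_delivery_weeks")


def test_overall_wald_p_present_and_bounded(small_cohort):
    fit = ClusterRelativeRisk(exposure="education").fit(small_cohort)
    assert 0.0 <= fit.overall_wald_p_ <= 1.0
    assert len(fit.estimates_) == 2  # two non-reference education levels
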