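"""Synthetic registry generator: determinism, marginals, oracles, validation."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neomort import schema
from neomort.cohort import build_cohort
from neomort.simulate import (
    ConfigError,
    RiskModel,
    SimulationConfig,
    generate_registry,
    small_config,
    summarize_truth,
    validate_config,
)
from neomort.variables import add_derived


def test_same_seed_identical_output():
    cfg = small_config()
    a = generate_registry(cfg, seed=99)
    b = generate_registry(cfg, seed=99)
    for x, y in zip(a[:3], b[:3]):
        pd.testing.assert_frame_equal(x, y)
    assert a[3].latent_causes.equals(b[3].latent_causes)


def test_different_seed_differs():
    cfg = small_config()
    a = generate_registry(cfg, seed=99)
    b = generate_registry(cfg, seed=100)
    assert not a[1].equals(b[1])


def test_seed_is_mandatory():
    with pytest.raises(ConfigError, match="seed"):
        generate_registry(small_config())


def test_cluster_structure_matches_config():
    cfg = small_config(n_clusters=7, deliveries=(30, 40), years=(2015, 2016))
    maternal, _, _, _ = generate_registry(cfg, seed=1)
    sizes = maternal.groupby(["cluster_id", "delivery_year"]).size()
    assert maternal["cluster_id"].nunique() == 7
    assert set(maternal["delivery_year"]) == {2015, 2016}
    assert sizes.between(30, 40).all()


def test_covariate_marginals_converge_at_scale():
    """Default-scale run: generated frequencies within 3 binomial SE."""
    cfg = SimulationConfig()
    maternal, _, _, _ = generate_registry(cfg, seed=2)
    n = len(maternal)
    for var, probs in cfg.covariate_marginals.items():
        freq = maternal[var].value_counts(normalize=True)
        for level, p in zip(schema.MATERNAL_ENUMS[var], probs):
            if p == 0:
                continue
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq.get(level, 0.0) - p) < 3 * se + 1e-3, (var, level)


def test_overall_death_risk_matches_enumeration_oracle():
    """Realized death risk vs brute-force enumeration over the covariate
    distribution (GA grid x weight bands x ANC levels, analytic cluster
    factor).  Tolerance covers binomial and cluster-effect Monte Carlo error."""
    cfg = SimulationConfig()
    maternal, infants, _, _ = generate_registry(cfg, seed=4)
    cohort = build_cohort(maternal, infants)
    realized = cohort.neonatal_deaths / cohort.live_births

    gd, wg, rm = cfg.ga_distribution, cfg.weight_given_ga, cfg.risk_model
    ga = np.linspace(gd.min_weeks, gd.max_weeks, 4000)
    pre = stats.norm.pdf(ga, gd.preterm_mean, gd.preterm_sd) * (ga < 37.0)
    term = stats.norm.pdf(ga, gd.term_mean, gd.term_sd) * (ga >= 37.0)
    dens = gd.preterm_prob * pre / np.trapezoid(pre, ga) + (
        1 - gd.preterm_prob
    ) * term / np.trapezoid(term, ga)
    mean_w = wg.mean_at_39_weeks + wg.slope_per_week * (ga - 39.0)
    edges = [-np.inf, 1000.0, 1500.0, 2500.0, np.inf]
    rr_bw = {"<1000": 25.6, "1000-1499": 19.8, "1500-2499": 3.1, ">=2500": 1.0}
    bw_factor = np.zeros_like(ga)
    for (lo, hi), band in zip(zip(edges, edges[1:]), rr_bw):
        p_band = stats.norm.cdf(hi, mean_w, wg.sd) - stats.norm.cdf(lo, mean_w, wg.sd)
        beta = rm.categorical_log_rr["birth_weight_band"].get(band, 0.0)
        bw_factor += p_band * math.exp(beta)
    e_bw = np.trapezoid(dens * bw_factor, ga)
    anc_probs = cfg.covariate_marginals["anc_visits_category"]
    e_anc = sum(
        p * math.exp(rm.categorical_log_rr["anc_visits_category"].get(level, 0.0))
        for level, p in zip(schema.ANC_LEVELS, anc_probs)
    )
    implied = math.exp(rm.intercept) * e_bw * e_anc * math.exp(rm.cluster_sd**2 / 2)
    assert abs(realized - implied) / implied < 0.20


def test_exclusion_cascade_reconciles(small_registry):
    maternal, infants, _, _ = small_registry
    cohort = build_cohort(maternal, infants)
    assert cohort.conserves_counts()


def test_summarize_truth_echoes_config():
    cfg = small_config()
    _, _, _, truth = generate_registry(cfg, seed=6)
    report = summarize_truth(truth)
    assert report["cause_mixture"] == pytest.approx(
        {
            "congenital_anomaly": 0.184,
            "infection": 0.237,
            "prematurity": 0.279,
            "asphyxia": 0.251,
            "unknown": 0.049,
        }
    )
    assert report["relative_risks"]["birth_weight_band[<1000]"] == pytest.approx(25.6)
    assert report["n_deaths"] == len(truth.latent_causes)


def test_zero_effect_config_reports_unit_risks():
    cfg = small_config(risk_model=RiskModel(categorical_log_rr={}))
    _, _, _, truth = generate_registry(cfg, seed=6)
    assert summarize_truth(truth)["relative_risks"] == {}


def test_latent_cause_mixture_tracks_target():
    cfg = small_config(n_clusters=20, deliveries=(300, 350))
    _, _, _, truth = generate_registry(cfg, seed=8)
    mixture = truth.latent_causes.value_counts(normalize=True)
    n = len(truth.latent_causes)
    for cause, p in cfg.cause_mixture.items():
        se = math.sqrt(p * (1 - p) / n)
        assert abs(mixture.get(cause, 0.0) - p) < 4 * se + 0.02, cause


def test_config_validation_errors():
    with pytest.raises(ConfigError, match="cause_mixture"):
        validate_config(replace(small_config(), cause_mixture={"infection": 1.0}))
    bad_marg = small_config()
    bad_marg.covariate_marginals["education"] = [0.5, 0.5, 0.5]
    with pytest.raises(ConfigError, match="education"):
        validate_config(bad_marg)
    with pytest.raises(ConfigError, match="sign_fidelity"):
        validate_config(replace(small_config(), sign_fidelity=1.5))
    # a risk model implying p >= 1 names the offending pattern
    hot = RiskModel(
        intercept=math.log(0.5),
        categorical_log_rr={"birth_weight_band": {"<1000": math.log(30.0)}},
    )
    with pytest.raises(ConfigError, match="birth_weight_band=<1000"):
        validate_config(replace(small_config(), risk_model=hot))


def test_enc_rates_conditional_on_status():
    cfg = small_config(n_clusters=20, deliveries=(300, 350))
    maternal, infants, _, _ = generate_registry(cfg, seed=9)
    cohort = build_cohort(maternal, infants)
    df = cohort.data
    died = df["alive_at_28d"] == False  # noqa: E712
    rate_died = (df.loc[died, "bag_mask"] == True).mean()  # noqa: E712
    rate_alive = (df.loc[~died, "bag_mask"] == True).mean()  # noqa: E712
    assert rate_died > 0.35 and rate_alive < 0.06


def test_twins_share_maternal_context():
    cfg = small_config(n_clusters=10, deliveries=(200, 250), twin_prob=0.05)
    _, infants, _, _ = generate_registry(cfg, seed=10)
    twins = infants[infants["multiple_gestation"] == True]  # noqa: E712
    per_mother = twins.groupby("mother_id")
    assert (per_mother.size() == 2).all()
    # delivered twins share gestational age (pregnancy losses have none)
    assert (per_mother["ga_delivery_weeks"].nunique() <= 1).all()
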