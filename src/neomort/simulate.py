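"""Seeded synthetic perinatal registry generator.

Emulates a prospective population-based pregnancy registry organised in
geographic study clusters (roughly 300-500 deliveries per cluster-year):
screened pregnancies with an enrollment exclusion cascade (non-resident
mothers, maternal death before delivery, miscarriage, medical termination,
stillbirth), maternal covariates drawn from configurable marginals,
gestational age from a term/preterm mixture with birth weight generated
conditional on gestational age, 28-day death from a log-link risk model with
a cluster-level random effect, a latent cause for each death that emits the
questionnaire sign indicators at a configurable fidelity, and essential
newborn care / treatment flags drawn conditional on vital status.

Default parameter values reproduce the marginal structure of a large rural
South-Asian registry cohort (2014-2018): a neonatal mortality rate near
24.5 per 1,000 live births, about 10% preterm deliveries, birth-weight band
frequencies near 0.4 / 0.8 / 19.9 / 79.0 percent, and a cause mixture of
18.4 / 23.7 / 27.9 / 25.1 / 4.9 percent across congenital anomaly,
infection, prematurity, asphyxia and unknown.

Covariates are drawn independently of one another (a stated
simplification); birth weight is the only covariate conditional on another
(gestational age).  Random streams are split per concern (structure,
covariates, outcomes, signs, care) so adding fields to one concern does not
perturb draws in another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import schema

# Table-style reference counts used for default covariate marginals
# (surviving-infant column of the maternal-characteristics table).
_DEFAULT_MARGINAL_COUNTS = {
    "age_category": [3842, 20299, 5309, 735],
    "education": [3555, 23434, 3194],
    "bmi_category": [10406, 17633, 2126],
    "parity_category": [11585, 16561, 2037],
    "anc_visits_category": [127, 914, 6152, 22990],
    "ga_at_enrollment_category": [10892, 11006, 6422, 1771],
    "delivery_attendant": [15192, 3212, 10996, 102, 589, 81, 9],
    "delivery_location": [21607, 7485, 753, 337],
}


def _normalized(counts) -> list:
    total = float(sum(counts))
    return [c / total for c in counts]


DEFAULT_COVARIATE_MARGINALS = {
    k: _normalized(v) for k, v in _DEFAULT_MARGINAL_COUNTS.items()
}

#: screened-pregnancy exclusion cascade fractions (sequential, as in an
#: enrollment diagram: 8578/47614 non-resident, 11/47614 maternal deaths,
#: then 4929 / 2542 / 884 of the remaining 39025 pregnancies)
DEFAULT_EXCLUSION_FRACTIONS = {
    "non_resident": 8578 / 47614,
    "maternal_death_before_delivery": 11 / 47614,
    "miscarriage": 4929 / 39025,
    "medical_termination": 2542 / 39025,
    "stillbirth": 884 / 39025,
}

#: target cause mixture conditional on death
DEFAULT_CAUSE_MIXTURE = {
    "congenital_anomaly": 0.184,
    "infection": 0.237,
    "prematurity": 0.279,
    "asphyxia": 0.251,
    "unknown": 0.049,
}

#: (rate among deaths, rate among survivors) per care/treatment flag
DEFAULT_ENC_TREATMENT_RATES = {
    "skin_to_skin": (0.088, 0.241),
    "bathed_within_6h": (0.004, 0.004),
    "breastfed_within_1h": (0.175, 0.700),
    "bag_mask": (0.503, 0.034),
    "antibiotics": (0.473, 0.061),
    "oxygen": (0.556, 0.054),
    "cpap": (0.195, 0.014),
    "mech_vent": (0.160, 0.005),
}


@dataclass(frozen=True)
class GADistribution:
    """Term/preterm mixture of gestational age at delivery (completed weeks)."""

    preterm_prob: float = 0.1046
    term_mean: float = 39.4
    term_sd: float = 1.3
    preterm_mean: float = 34.4
    preterm_sd: float = 2.2
    min_weeks: float = 22.0
    max_weeks: float = 43.0


@dataclass(frozen=True)
class WeightGivenGA:
    """Linear conditional mean of birth weight (g) given gestational age."""

    mean_at_39_weeks: float = 2890.0
    slope_per_week: float = 165.0
    sd: float = 380.0
    min_g: float = 300.0
    max_g: float = 5500.0


@dataclass(frozen=True)
class RiskModel:
    """Log-link model of 28-day death for live births.

    ``log p = intercept + sum(categorical effects) + ga_slope * (ga_ref - ga)
    + year effect + cluster effect``.  The intercept is the log baseline risk
    at the reference pattern.
    """

    intercept: float = math.log(0.0135)
    categorical_log_rr: dict = field(
        default_factory=lambda: {
            "birth_weight_band": {
                "<1000": math.log(25.6),
                "1000-1499": math.log(19.8),
                "1500-2499": math.log(3.1),
            },
            "anc_visits_category": {
                "0-1": math.log(1.6),
                "2": math.log(1.4),
                "3": math.log(1.2),
            },
        }
    )
    ga_log_rr_per_week_decrease: float = 0.0
    ga_reference_weeks: float = 40.0
    year_log_rr: dict = field(default_factory=dict)
    cluster_sd: float = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; the seed is mandatory at generation."""

    n_clusters: int = 20
    deliveries_per_cluster_year: tuple = (300, 500)
    years: tuple = (2014, 2015, 2016, 2017, 2018)
    exclusion_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_FRACTIONS)
    )
    covariate_marginals: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_COVARIATE_MARGINALS.items()}
    )
    covariate_missing_rate: float = 0.001
    pregnancy_complication_rate: float = 0.15
    twin_prob: float = 286 / 30657
    ga_distribution: GADistribution = field(default_factory=GADistribution)
    weight_given_ga: WeightGivenGA = field(default_factory=WeightGivenGA)
    risk_model: RiskModel = field(default_factory=RiskModel)
    cause_mixture: dict = field(default_factory=lambda: dict(DEFAULT_CAUSE_MIXTURE))
    sign_fidelity: float = 0.95
    cod_form_missing_rate: float = 8 / 758
    enc_treatment_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_ENC_TREATMENT_RATES)
    )


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


def validate_config(config: SimulationConfig) -> None:
    for name, probs in config.covariate_marginals.items():
        levels = schema.MATERNAL_ENUMS.get(name)
        if levels is None or len(levels) != len(probs):
            raise ConfigError(f"marginals for {name!r} do not match its levels")
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-8:
            raise ConfigError(f"marginals for {name!r} must be a probability vector")
    mix = config.cause_mixture
    if set(mix) != set(schema.CAUSE_LEVELS) or abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ConfigError("cause_mixture must cover the five causes and sum to 1")
    if not 0.0 <= config.sign_fidelity <= 1.0:
        raise ConfigError("sign_fidelity must be in [0, 1]")
    for reason, p in config.exclusion_fractions.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"exclusion fraction {reason!r} outside [0, 1]")
    # worst-case deterministic risk must stay below 1
    rm = config.risk_model
    worst = rm.intercept
    pattern = ["reference"]
    for var, effects in rm.categorical_log_rr.items():
        best_level, best = max(effects.items(), key=lambda kv: kv[1])
        if best > 0:
            worst += best
            pattern.append(f"{var}={best_level}")
    if rm.ga_log_rr_per_week_decrease > 0:
        ga_min = config.ga_distribution.min_weeks
        worst += rm.ga_log_rr_per_week_decrease * (rm.ga_reference_weeks - ga_min)
        pattern.append(f"ga_delivery_weeks={ga_min}")
    if rm.year_log_rr:
        worst += max(0.0, max(rm.year_log_rr.values()))
    if worst >= 0.0:
        raise ConfigError(
            "risk model implies death probability >= 1 for covariate pattern "
            + " & ".join(pattern)
        )


@dataclass
class TrueParameters:
    """Generating values retained alongside each dataset for recovery tests."""

    risk_model: RiskModel
    cluster_effects: dict
    latent_causes: pd.Series  # indexed by infant_id, deaths only
    cause_mixture: dict
    sign_fidelity: float
    config: SimulationConfig


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Normal draws truncated by resampling (bounded retry, then clip)."""
    x = rng.normal(mean, sd, size)
    for _ in range(20):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(x, lo, hi)


def _weight_band(w):
    return np.select(
        [w < 1000, w < 1500, w < 2500], ["<1000", "1000-1499", "1500-2499"], ">=2500"
    )


def _allowed_causes(ga: float) -> list:
    """Causes whose sign pattern the hierarchy can recover at this GA."""
    if ga >= 37.0:
        return ["congenital_anomaly", "infection", "asphyxia", "unknown"]
    if ga >= 34.0:
        return ["congenital_anomaly", "infection", "asphyxia", "prematurity"]
    return ["congenital_anomaly", "infection", "prematurity"]


def generate_registry(
    config: Optional[SimulationConfig] = None, seed: Optional[int] = None
):
    """Generate (maternal, infant, cod) tables plus the generating truth.

    Fully reproducible from ``seed``; the same seed yields identical tables.
    """
    config = config or SimulationConfig()
    validate_config(config)
    if seed is None:
        raise ConfigError("a seed is mandatory")
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_struct = np.random.default_rng(streams[0])
    rng_cov = np.random.default_rng(streams[1])
    rng_out = np.random.default_rng(streams[2])
    rng_sign = np.random.default_rng(streams[3])
    rng_enc = np.random.default_rng(streams[4])

    lo, hi = config.deliveries_per_cluster_year
    rows = []
    for c in range(config.n_clusters):
        for year in config.years:
            n = int(rng_struct.integers(lo, hi + 1))
            rows.append((f"C{c:02d}", year, n))
    cluster_ids = np.concatenate([[cid] * n for cid, _, n in rows])
    years = np.concatenate([[yr] * n for _, yr, n in rows])
    n_preg = len(cluster_ids)
    mother_ids = np.array([f"M{i:06d}" for i in range(n_preg)])

    # ---- maternal covariates ------------------------------------------------
    maternal = pd.DataFrame(
        {
            "mother_id": mother_ids,
            "cluster_id": cluster_ids,
            "delivery_year": years.astype(int),
        }
    )
    for var, probs in config.covariate_marginals.items():
        levels = schema.MATERNAL_ENUMS[var]
        draws = rng_cov.choice(len(levels), size=n_preg, p=probs)
        vals = pd.Series(np.asarray(levels, object)[draws], index=maternal.index)
        if config.covariate_missing_rate > 0:
            miss = rng_cov.random(n_preg) < config.covariate_missing_rate
            vals[miss] = pd.NA
        maternal[var] = vals
    maternal["pregnancy_complication"] = (
        rng_cov.random(n_preg) < config.pregnancy_complication_rate
    )

    # ---- exclusion cascade --------------------------------------------------
    frac = config.exclusion_fractions
    non_resident = rng_struct.random(n_preg) < frac["non_resident"]
    mat_death = rng_struct.random(n_preg) < frac["maternal_death_before_delivery"]
    maternal["resident_in_cluster"] = ~non_resident
    maternal["died_before_delivery"] = mat_death

    p_mis = frac["miscarriage"]
    p_mtp = frac["medical_termination"]
    p_sb = frac["stillbirth"]
    u = rng_struct.random(n_preg)
    outcome = np.where(
        u < p_mis,
        "miscarriage",
        np.where(
            u < p_mis + p_mtp,
            "medical_termination",
            np.where(u < p_mis + p_mtp + p_sb, "stillbirth", "live_birth"),
        ),
    )

    # ---- infants (twins duplicate the pregnancy row) ------------------------
    twins = rng_struct.random(n_preg) < config.twin_prob
    preg_idx = np.repeat(np.arange(n_preg), np.where(twins, 2, 1))
    n_inf = len(preg_idx)
    birth_order = np.ones(n_inf, int)
    birth_order[1:][preg_idx[1:] == preg_idx[:-1]] = 2
    infant_ids = np.array(
        [f"I{pi:06d}-{bo}" for pi, bo in zip(preg_idx, birth_order)]
    )
    inf_outcome = outcome[preg_idx]
    inf_cluster = cluster_ids[preg_idx]
    inf_year = years[preg_idx].astype(int)
    live = inf_outcome == "live_birth"
    delivered = live | (inf_outcome == "stillbirth")

    gd = config.ga_distribution
    is_preterm = rng_cov.random(n_inf) < gd.preterm_prob
    ga = np.where(
        is_preterm,
        _truncnorm(rng_cov, gd.preterm_mean, gd.preterm_sd, gd.min_weeks, 36.9, n_inf),
        _truncnorm(rng_cov, gd.term_mean, gd.term_sd, 37.0, gd.max_weeks, n_inf),
    )
    # twins share gestational age
    second = birth_order == 2
    ga[second] = ga[np.flatnonzero(second) - 1]
    ga = np.round(ga, 1)

    wg = config.weight_given_ga
    wt_mean = wg.mean_at_39_weeks + wg.slope_per_week * (ga - 39.0)
    weight = _truncnorm(rng_cov, 0.0, 1.0, -4.0, 4.0, n_inf) * wg.sd + wt_mean
    weight = np.clip(np.round(weight), wg.min_g, wg.max_g)

    # ---- 28-day death among live births ------------------------------------
    rm = config.risk_model
    cluster_labels = sorted(set(cluster_ids))
    u_cluster = {
        cid: float(rng_out.normal(0.0, rm.cluster_sd)) for cid in cluster_labels
    }
    eta = np.full(n_inf, rm.intercept)
    bands = _weight_band(weight)
    for var, effects in rm.categorical_log_rr.items():
        if var == "birth_weight_band":
            vals = bands
        else:
            vals = maternal[var].to_numpy(object)[preg_idx]
        for level, beta in effects.items():
            # a missing covariate contributes no effect (reference-like)
            ind = pd.Series(vals).eq(level).fillna(False).to_numpy(bool)
            eta = eta + beta * ind
    if rm.ga_log_rr_per_week_decrease:
        eta = eta + rm.ga_log_rr_per_week_decrease * (rm.ga_reference_weeks - ga)
    for year, beta in rm.year_log_rr.items():
        eta = eta + beta * (inf_year == int(year))
    eta = eta + np.array([u_cluster[c] for c in inf_cluster])
    p_death = np.minimum(np.exp(eta), 1.0 - 1e-12)
    died = (rng_out.random(n_inf) < p_death) & live

    age_at_death = np.minimum(rng_out.geometric(0.15, n_inf) - 1, 27)
    cod_form = rng_out.random(n_inf) >= config.cod_form_missing_rate

    # ---- latent causes and questionnaire signs ------------------------------
    mix = config.cause_mixture
    fid = config.sign_fidelity
    causes = np.full(n_inf, None, dtype=object)
    signs = {f: np.zeros(n_inf, bool) for f in schema.COD_FLAGS}
    infection_mix = (
        ["sepsis", "pneumonia", "omphalitis", "infection_suspected", "tetanus"],
        [0.45, 0.30, 0.10, 0.10, 0.05],
    )
    # The hierarchy cannot recover every cause at every gestational age
    # (e.g. prematurity needs a preterm death), so per-stratum cause
    # probabilities are fitted by iterative proportional fitting: row totals
    # are the death counts per GA stratum, column targets the configured
    # mixture, support the recoverable causes per stratum.
    death_idx = np.flatnonzero(died)
    strata = [_allowed_causes(g) for g in (39.0, 35.0, 30.0)]
    stratum_of = np.where(ga >= 37.0, 0, np.where(ga >= 34.0, 1, 2))
    row_totals = np.array([(stratum_of[death_idx] == s).sum() for s in range(3)], float)
    support = np.array(
        [[c in strata[s] for c in schema.CAUSE_LEVELS] for s in range(3)], float
    )
    col_targets = np.array([mix[c] for c in schema.CAUSE_LEVELS]) * len(death_idx)
    m = support * np.outer(row_totals, col_targets)
    for _ in range(200):
        rs = m.sum(axis=1, keepdims=True)
        m = np.divide(m * row_totals[:, None], rs, out=m, where=rs > 0)
        cs = m.sum(axis=0, keepdims=True)
        m = np.divide(m * col_targets[None, :], cs, out=m, where=cs > 0)
    rs = m.sum(axis=1, keepdims=True)
    probs_by_stratum = np.divide(m, rs, out=np.zeros_like(m), where=rs > 0)
    for i in rng_sign.permutation(death_idx):
        p = probs_by_stratum[stratum_of[i]]
        if p.sum() <= 0:  # pragma: no cover - empty stratum
            p = np.array([mix[c] for c in schema.CAUSE_LEVELS]) * support[stratum_of[i]]
        cause = rng_sign.choice(schema.CAUSE_LEVELS, p=p / p.sum())
        causes[i] = cause
        if cause == "congenital_anomaly":
            if rng_sign.random() < fid:
                signs["major_congenital_anomaly"][i] = True
        elif cause == "infection":
            if rng_sign.random() < fid:
                sign = rng_sign.choice(infection_mix[0], p=infection_mix[1])
                signs[sign][i] = True
        elif cause == "asphyxia":
            if rng_sign.random() < fid:
                if ga[i] >= 37.0 or rng_sign.random() < 0.6:
                    signs["breathing_difficulty_at_birth"][i] = True
                    if rng_sign.random() < 0.5:
                        signs["respiratory_distress"][i] = True
                else:
                    signs["maternal_pregnancy_complication"][i] = True
        # prematurity and unknown emit no positive signs

    # ---- newborn care and treatment flags -----------------------------------
    enc = {}
    for flag, (rate_died, rate_alive) in config.enc_treatment_rates.items():
        p = np.where(died, rate_died, rate_alive)
        enc[flag] = rng_enc.random(n_inf) < p

    # ---- assemble typed tables ----------------------------------------------
    def _mask(series_vals, cond, dtype="boolean"):
        s = pd.Series(list(series_vals), dtype=object)
        s[~cond] = pd.NA
        return s.astype(dtype)

    infants = pd.DataFrame({"infant_id": infant_ids, "mother_id": mother_ids[preg_idx]})
    infants["birth_outcome"] = inf_outcome
    infants["birth_weight_g"] = _mask(weight, delivered, "Float64")
    infants["ga_delivery_weeks"] = _mask(ga, delivered, "Float64")
    infants["multiple_gestation"] = pd.Series(twins[preg_idx]).astype("boolean")
    infants["alive_at_28d"] = _mask(~died, live)
    infants["age_at_death_days"] = _mask(age_at_death, died, "Int64")
    for flag in [
        "skin_to_skin",
        "bathed_within_6h",
        "breastfed_within_1h",
        "bag_mask",
        "antibiotics",
        "oxygen",
        "cpap",
        "mech_vent",
    ]:
        infants[flag] = _mask(enc[flag], live)
    infants["cod_form_available"] = _mask(cod_form, died)

    maternal = maternal[list(schema.MATERNAL_COLUMNS)].copy()
    for flag in schema.MATERNAL_FLAGS:
        maternal[flag] = maternal[flag].astype("boolean")

    has_cod = died & cod_form
    cod = pd.DataFrame({"infant_id": infant_ids[has_cod]})
    for flag in schema.COD_FLAGS:
        cod[flag] = pd.Series(signs[flag][has_cod]).astype("boolean")
    cod["ga_delivery_weeks"] = pd.Series(ga[has_cod]).astype("Float64")
    cod["birth_weight_g"] = pd.Series(weight[has_cod]).astype("Float64")
    cod = cod[list(schema.COD_COLUMNS)]

    truth = TrueParameters(
        risk_model=rm,
        cluster_effects=u_cluster,
        latent_causes=pd.Series(causes[died], index=infant_ids[died], name="cause"),
        cause_mixture=dict(mix),
        sign_fidelity=fid,
        config=config,
    )
    return maternal, infants, cod, truth


def summarize_truth(params: TrueParameters) -> dict:
    """Generating relative risks and cause mixture, for recovery tests."""
    rm = params.risk_model
    rrs = {
        f"{var}[{level}]": math.exp(beta)
        for var, effects in rm.categorical_log_rr.items()
        for level, beta in effects.items()
    }
    if rm.ga_log_rr_per_week_decrease:
        rrs["ga_delivery_weeks_per_week_decrease"] = math.exp(
            rm.ga_log_rr_per_week_decrease
        )
    return {
        "baseline_risk": math.exp(rm.intercept),
        "relative_risks": rrs,
        "cluster_sd": rm.cluster_sd,
        "cause_mixture": dict(params.cause_mixture),
        "sign_fidelity": params.sign_fidelity,
        "n_deaths": int(len(params.latent_causes)),
    }


def small_config(
    n_clusters: int = 10,
    deliveries: tuple = (40, 60),
    years: tuple = (2014,),
    **overrides,
) -> SimulationConfig:
    """A reduced-scale configuration for fast tests and examples."""
    return replace(
        SimulationConfig(),
        n_clusters=n_clusters,
        deliveries_per_cluster_year=deliveries,
        years=years,
        **overrides,
    )
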