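import numpy as np
import pandas as pd
import pytest

from neomort.cohort import build_cohort
from neomort.simulate import generate_registry, small_config


def mk_maternal(n, **overrides):
    """Minimal valid maternal table with sensible defaults."""
    base = {
        "mother_id": [f"M{i}" for i in range(n)],
        "cluster_id": ["C0"] * n,
        "delivery_year": [2014] * n,
        "resident_in_cluster": [True] * n,
        "died_before_delivery": [False] * n,
        "age_category": ["20-25"] * n,
        "education": ["primary_secondary"] * n,
        "bmi_category": ["normal"] * n,
        "parity_category": ["1-2"] * n,
        "anc_visits_category": ["4+"] * n,
        "ga_at_enrollment_category": ["<8"] * n,
        "delivery_attendant": ["obstetrician"] * n,
        "delivery_location": ["hospital"] * n,
        "pregnancy_complication": [False] * n,
    }
    base.update(overrides)
    df = pd.DataFrame(base)
    for c in ("resident_in_cluster", "died_before_delivery", "pregnancy_complication"):
        df[c] = df[c].astype("boolean")
    return df


def mk_infants(mother_ids, **overrides):
    """Minimal valid infant table, one live birth per mother by default."""
    n = len(mother_ids)
    base = {
        "infant_id": [f"I{i}" for i in range(n)],
        "mother_id": list(mother_ids),
        "birth_outcome": ["live_birth"] * n,
        "birth_weight_g": [3000.0] * n,
        "ga_delivery_weeks": [39.0] * n,
        "multiple_gestation": [False] * n,
        "alive_at_28d": [True] * n,
        "age_at_death_days": [pd.NA] * n,
        "skin_to_skin": [True] * n,
        "bathed_within_6h": [False] * n,
        "breastfed_within_1h": [True] * n,
        "bag_mask": [False] * n,
        "antibiotics": [False] * n,
        "oxygen": [False] * n,
        "cpap": [False] * n,
        "mech_vent": [False] * n,
        "cod_form_available": [pd.NA] * n,
    }
    base.update(overrides)
    df = pd.DataFrame(base)
    for c in df.columns:
        if c in ("birth_weight_g", "ga_delivery_weeks"):
            df[c] = df[c].astype("Float64")
        elif c == "age_at_death_days":
            df[c] = df[c].astype("Int64")
        elif c not in ("infant_id", "mother_id", "birth_outcome"):
            df[c] = df[c].astype("boolean")
    return df


@pytest.fixture(scope="session")
def small_registry():
    cfg = small_config(n_clusters=12, deliveries=(150, 200))
    return generate_registry(cfg, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_registry):
    maternal, infants, _, _ = small_registry
    return build_cohort(maternal, infants)
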