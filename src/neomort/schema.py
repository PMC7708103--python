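"""Registry table schemas: column sets, categorical level dictionaries, validation.

Three tabular inputs describe a perinatal registry: a maternal table (one row
per enrolled pregnancy), an infant table (one row per birth; multiples each get
a row) and a cause-of-death questionnaire table (one row per neonatal death
with a completed form).  Files are UTF-8 CSV; a missing value is an empty
field.  Readers reject files whose header set does not match the declared
schema version.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

# -- categorical level dictionaries -----------------------------------------

AGE_LEVELS = ["<20", "20-25", "26-30", ">30"]
EDUCATION_LEVELS = ["no_formal", "primary_secondary", "university_plus"]
BMI_LEVELS = ["underweight", "normal", "overweight"]
PARITY_LEVELS = ["0", "1-2", "3+"]
ANC_LEVELS = ["0-1", "2", "3", "4+"]
GA_ENROLL_LEVELS = ["<8", "8-11.6", "12-20", ">20"]
ATTENDANT_LEVELS = [
    "obstetrician",
    "non_ob_physician",
    "nurse_midwife",
    "tba",
    "family",
    "self",
    "other",
]
LOCATION_LEVELS = ["hospital", "clinic_health_center", "home", "other"]
OUTCOME_LEVELS = ["live_birth", "stillbirth", "miscarriage", "medical_termination"]

#: the five causes the hierarchical algorithm can assign
CAUSE_LEVELS = ["congenital_anomaly", "infection", "prematurity", "asphyxia", "unknown"]

MATERNAL_ENUMS = {
    "age_category": AGE_LEVELS,
    "education": EDUCATION_LEVELS,
    "bmi_category": BMI_LEVELS,
    "parity_category": PARITY_LEVELS,
    "anc_visits_category": ANC_LEVELS,
    "ga_at_enrollment_category": GA_ENROLL_LEVELS,
    "delivery_attendant": ATTENDANT_LEVELS,
    "delivery_location": LOCATION_LEVELS,
}

INFANT_ENUMS = {"birth_outcome": OUTCOME_LEVELS}

MATERNAL_FLAGS = ["resident_in_cluster", "died_before_delivery", "pregnancy_complication"]
INFANT_FLAGS = [
    "multiple_gestation",
    "alive_at_28d",
    "skin_to_skin",
    "bathed_within_6h",
    "breastfed_within_1h",
    "bag_mask",
    "antibiotics",
    "oxygen",
    "cpap",
    "mech_vent",
    "cod_form_available",
]
COD_FLAGS = [
    "major_congenital_anomaly",
    "tetanus",
    "omphalitis",
    "sepsis",
    "pneumonia",
    "infection_suspected",
    "breathing_difficulty_at_birth",
    "respiratory_distress",
    "maternal_pregnancy_complication",
]

MATERNAL_COLUMNS = [
    "mother_id",
    "cluster_id",
    "delivery_year",
    "resident_in_cluster",
    "died_before_delivery",
    "age_category",
    "education",
    "bmi_category",
    "parity_category",
    "anc_visits_category",
    "ga_at_enrollment_category",
    "delivery_attendant",
    "delivery_location",
    "pregnancy_complication",
]

INFANT_COLUMNS = [
    "infant_id",
    "mother_id",
    "birth_outcome",
    "birth_weight_g",
    "ga_delivery_weeks",
    "multiple_gestation",
    "alive_at_28d",
    "age_at_death_days",
    "skin_to_skin",
    "bathed_within_6h",
    "breastfed_within_1h",
    "bag_mask",
    "antibiotics",
    "oxygen",
    "cpap",
    "mech_vent",
    "cod_form_available",
]

COD_COLUMNS = [
    "infant_id",
    "major_congenital_anomaly",
    "tetanus",
    "omphalitis",
    "sepsis",
    "pneumonia",
    "infection_suspected",
    "ga_delivery_weeks",
    "birth_weight_g",
    "breathing_difficulty_at_birth",
    "respiratory_distress",
    "maternal_pregnancy_complication",
]

BIRTH_WEIGHT_RANGE_G = (200.0, 6000.0)
MIN_GA_WEEKS = 20.0


class SchemaError(ValueError):
    """A table violates the declared schema (header, enum value or range)."""


@dataclass(frozen=True)
class SchemaVersion:
    """Declared table layout for one schema version."""

    version: str = SCHEMA_VERSION
    maternal_columns: tuple = tuple(MATERNAL_COLUMNS)
    infant_columns: tuple = tuple(INFANT_COLUMNS)
    cod_columns: tuple = tuple(COD_COLUMNS)
    enums: dict = field(
        default_factory=lambda: {**MATERNAL_ENUMS, **INFANT_ENUMS, "cause": CAUSE_LEVELS}
    )

    def columns_for(self, table: str) -> tuple:
        try:
            return {
                "maternal": self.maternal_columns,
                "infant": self.infant_columns,
                "cod": self.cod_columns,
            }[table]
        except KeyError:  # pragma: no cover - programmer error
            raise ValueError(f"unknown table {table!r}")


DEFAULT_SCHEMA = SchemaVersion()


def check_header(columns, table: str, schema: SchemaVersion = DEFAULT_SCHEMA) -> None:
    """Reject a header whose column *set* differs from the declared schema."""
    expected, got = set(schema.columns_for(table)), set(columns)
    if expected != got:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise SchemaError(
            f"{table} table header does not match schema v{schema.version}: "
            f"missing {missing}, unexpected {extra}"
        )


def _check_enum(df: pd.DataFrame, column: str, levels, table: str) -> None:
    if column not in df.columns:
        return
    vals = df[column]
    bad = vals.notna() & ~vals.isin(levels)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{table} table, column {column!r}, row {row}: "
            f"value {vals.iloc[row]!r} not in {levels}"
        )


def validate_maternal(df: pd.DataFrame, schema: SchemaVersion = DEFAULT_SCHEMA) -> None:
    check_header(df.columns, "maternal", schema)
    for col, levels in MATERNAL_ENUMS.items():
        _check_enum(df, col, levels, "maternal")
    if df["mother_id"].duplicated().any():
        dup = df.loc[df["mother_id"].duplicated(), "mother_id"].iloc[0]
        raise SchemaError(f"duplicate mother_id {dup!r} in maternal table")
    if (df["cluster_id"].isna() | (df["cluster_id"].astype(str) == "")).any():
        raise SchemaError("maternal table contains an empty cluster_id")


def validate_infant(df: pd.DataFrame, schema: SchemaVersion = DEFAULT_SCHEMA) -> None:
    check_header(df.columns, "infant", schema)
    for col, levels in INFANT_ENUMS.items():
        _check_enum(df, col, levels, "infant")
    if df["infant_id"].duplicated().any():
        dup = df.loc[df["infant_id"].duplicated(), "infant_id"].iloc[0]
        raise SchemaError(f"duplicate infant_id {dup!r} in infant table")
    bw = pd.to_numeric(df["birth_weight_g"], errors="coerce")
    lo, hi = BIRTH_WEIGHT_RANGE_G
    bad = bw.notna() & ((bw < lo) | (bw > hi))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"infant table, column 'birth_weight_g', row {row}: "
            f"{bw.iloc[row]} g outside [{lo}, {hi}]"
        )
    # age at death present iff the infant died
    died = df["alive_at_28d"] == False  # noqa: E712 - nullable boolean
    has_age = pd.to_numeric(df["age_at_death_days"], errors="coerce").notna()
    mismatch = died.fillna(False) != has_age
    if mismatch.any():
        row = int(np.flatnonzero(mismatch.to_numpy())[0])
        raise SchemaError(
            f"infant table row {row}: age_at_death_days must be present "
            "if and only if alive_at_28d is false"
        )


def validate_cod(df: pd.DataFrame, schema: SchemaVersion = DEFAULT_SCHEMA) -> None:
    check_header(df.columns, "cod", schema)
    if df["infant_id"].duplicated().any():
        dup = df.loc[df["infant_id"].duplicated(), "infant_id"].iloc[0]
        raise SchemaError(f"duplicate infant_id {dup!r} in cod table")
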