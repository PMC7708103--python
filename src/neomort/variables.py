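"""Analysis variables: references, derived bands, and design-matrix building.

Maps registry columns (and a few derived ones: birth-weight bands, preterm
indicator) to model terms.  Categorical variables enter as indicator
contrasts against a designated reference level; gestational age at delivery
enters negated so its exponentiated coefficient is the relative risk per
one-week *decrease*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import schema

BIRTH_WEIGHT_BAND_LEVELS = ["<1000", "1000-1499", "1500-2499", ">=2500"]
BIRTH_WEIGHT_BAND_EDGES = (1000.0, 1500.0, 2500.0)
PRETERM_CUTOFF_WEEKS = 37.0


def birth_weight_band(weights: pd.Series) -> pd.Series:
    """Band birth weight in grams into the four standard categories."""
    w = pd.to_numeric(weights, errors="coerce")
    out = pd.Series(pd.NA, index=w.index, dtype=object)
    lo, mid, hi = BIRTH_WEIGHT_BAND_EDGES
    out[w < lo] = "<1000"
    out[(w >= lo) & (w < mid)] = "1000-1499"
    out[(w >= mid) & (w < hi)] = "1500-2499"
    out[w >= hi] = ">=2500"
    return out


def add_derived(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived analysis columns (idempotent, copy-on-write)."""
    out = df.copy()
    out["birth_weight_band"] = birth_weight_band(df["birth_weight_g"])
    ga = pd.to_numeric(df["ga_delivery_weeks"], errors="coerce")
    preterm = pd.Series(pd.NA, index=df.index, dtype=object)
    preterm[ga >= PRETERM_CUTOFF_WEEKS] = False
    preterm[ga < PRETERM_CUTOFF_WEEKS] = True
    out["preterm"] = preterm
    return out


def death_indicator(df: pd.DataFrame) -> pd.Series:
    """1.0 for a neonatal death before day 28, 0.0 for alive, NaN if unknown."""
    alive = df["alive_at_28d"]
    y = pd.Series(np.nan, index=df.index)
    y[alive == True] = 0.0  # noqa: E712
    y[alive == False] = 1.0  # noqa: E712
    return y


@dataclass(frozen=True)
class VariableSpec:
    """How one analysis variable enters a risk model."""

    name: str
    kind: str  # "categorical" | "binary" | "continuous"
    levels: Optional[tuple] = None
    reference: Optional[str] = None
    negate: bool = False  # continuous only: effect per one-unit decrease


def _cat(name: str, levels, reference: str) -> VariableSpec:
    return VariableSpec(name, "categorical", tuple(levels), reference)


VARIABLE_SPECS: dict[str, VariableSpec] = {
    "age_category": _cat("age_category", schema.AGE_LEVELS, "20-25"),
    "education": _cat("education", schema.EDUCATION_LEVELS, "university_plus"),
    "bmi_category": _cat("bmi_category", schema.BMI_LEVELS, "normal"),
    "parity_category": _cat("parity_category", schema.PARITY_LEVELS, "1-2"),
    "anc_visits_category": _cat("anc_visits_category", schema.ANC_LEVELS, "4+"),
    "ga_at_enrollment_category": _cat(
        "ga_at_enrollment_category", schema.GA_ENROLL_LEVELS, "<8"
    ),
    "birth_weight_band": _cat("birth_weight_band", BIRTH_WEIGHT_BAND_LEVELS, ">=2500"),
    "preterm": VariableSpec("preterm", "binary"),
    "multiple_gestation": VariableSpec("multiple_gestation", "binary"),
    "skin_to_skin": VariableSpec("skin_to_skin", "binary"),
    "bathed_within_6h": VariableSpec("bathed_within_6h", "binary"),
    "breastfed_within_1h": VariableSpec("breastfed_within_1h", "binary"),
    "ga_delivery_weeks": VariableSpec("ga_delivery_weeks", "continuous", negate=True),
}


def get_spec(variable: str, reference: Optional[str] = None) -> VariableSpec:
    if variable not in VARIABLE_SPECS:
        raise KeyError(
            f"unknown analysis variable {variable!r}; "
            f"valid names: {sorted(VARIABLE_SPECS)}"
        )
    spec = VARIABLE_SPECS[variable]
    if reference is not None and spec.kind == "categorical":
        if reference not in spec.levels:
            raise ValueError(f"{reference!r} is not a level of {variable!r}")
        spec = VariableSpec(spec.name, spec.kind, spec.levels, reference)
    return spec


@dataclass
class Design:
    """A built design matrix with term bookkeeping."""

    exog: np.ndarray  # (n, p) with leading intercept
    names: list  # term names, names[0] == "intercept"
    terms: dict = field(default_factory=dict)  # variable -> column index list
    index: Optional[pd.Index] = None  # rows of the source frame retained


def build_design(df: pd.DataFrame, variables: list, references: Optional[dict] = None) -> Design:
    """Complete-case design matrix for the listed variables.

    Rows missing any listed variable are dropped (complete case across the
    model's variables, mirroring how multivariable tables report a common
    denominator).
    """
    references = references or {}
    specs = [get_spec(v, references.get(v)) for v in variables]
    cols: dict[str, pd.Series] = {}
    for spec in specs:
        s = df[spec.name]
        if spec.kind == "continuous":
            cols[spec.name] = pd.to_numeric(s, errors="coerce")
        else:
            cols[spec.name] = s
    frame = pd.DataFrame(cols, index=df.index).dropna()

    names = ["intercept"]
    terms: dict[str, list] = {}
    mats = [np.ones(len(frame))]
    for spec in specs:
        start = len(names)
        if spec.kind == "categorical":
            for level in spec.levels:
                if level == spec.reference:
                    continue
                mats.append((frame[spec.name] == level).to_numpy(float))
                names.append(f"{spec.name}[{level}]")
        elif spec.kind == "binary":
            mats.append((frame[spec.name] == True).to_numpy(float))  # noqa: E712
            names.append(spec.name)
        else:
            x = frame[spec.name].to_numpy(float)
            mats.append(-x if spec.negate else x)
            names.append(
                f"{spec.name}_per_unit_decrease" if spec.negate else spec.name
            )
        terms[spec.name] = list(range(start, len(names)))
    exog = np.column_stack(mats)
    return Design(exog=exog, names=names, terms=terms, index=frame.index)
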