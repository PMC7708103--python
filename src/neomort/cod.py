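"""Hierarchical cause-of-death assignment for neonatal deaths.

The classifier applies a fixed decision hierarchy to questionnaire-derived
sign indicators, assigning exactly one of five causes per death:

1. A major congenital anomaly, if present, is the cause regardless of any
   other finding.
2. Otherwise, any present or suspected infection (tetanus, omphalitis,
   sepsis, pneumonia, or a general suspicion flag) is the cause.
3. Otherwise the assignment is banded on gestational age at delivery, with
   birth weight as the fallback when gestational age is missing:

   * term (>= 37 completed weeks; fallback >= 2500 g): asphyxia if there
     were signs of breathing difficulty at birth or respiratory distress,
     else unknown;
   * moderate preterm (34 to < 37 weeks; fallback 2000 to < 2500 g):
     asphyxia if there was breathing difficulty and/or any maternal
     pregnancy complication, else complications of prematurity;
   * early preterm (< 34 weeks; fallback < 2000 g): complications of
     prematurity.

A death with neither gestational age nor birth weight cannot be banded and
is assigned unknown with a warning.  Every assignment carries a rule
provenance code so audits can isolate, e.g., moderate-preterm deaths that
fell through to prematurity with no positive sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .schema import CAUSE_LEVELS

# band boundaries (completed weeks / grams); weight applies only when GA missing
TERM_GA_WEEKS = 37.0
MODERATE_PRETERM_GA_WEEKS = 34.0
TERM_WEIGHT_G = 2500.0
MODERATE_PRETERM_WEIGHT_G = 2000.0

INFECTION_SIGNS = ("tetanus", "omphalitis", "sepsis", "pneumonia", "infection_suspected")
BREATHING_SIGNS = ("breathing_difficulty_at_birth", "respiratory_distress")

#: rule provenance codes, in hierarchy order
RULE_ANOMALY = "anomaly"
RULE_INFECTION = "infection"
RULE_TERM_ASPHYXIA = "term_asphyxia"
RULE_TERM_UNKNOWN = "term_unknown"
RULE_BAND_ASPHYXIA = "moderate_preterm_asphyxia"
RULE_EARLY_PRETERM = "early_preterm"
RULE_BAND_RESIDUAL = "moderate_preterm_no_signs"
RULE_UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class CODInput:
    """Sign indicators and anthropometry consumed by the cause hierarchy.

    A record is classifiable when at least one of ``ga_delivery_weeks`` /
    ``birth_weight_g`` is present.
    """

    major_congenital_anomaly: bool = False
    tetanus: bool = False
    omphalitis: bool = False
    sepsis: bool = False
    pneumonia: bool = False
    infection_suspected: bool = False
    ga_delivery_weeks: Optional[float] = None
    birth_weight_g: Optional[float] = None
    breathing_difficulty_at_birth: bool = False
    respiratory_distress: bool = False
    maternal_pregnancy_complication: bool = False


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or x is pd.NA


def _flag(record, name: str) -> bool:
    v = record.get(name, False) if isinstance(record, Mapping) else getattr(record, name)
    return bool(v) if not _is_missing(v) else False


def assign_cause(record) -> tuple[str, str]:
    """Assign one cause of death, returning ``(cause, rule_code)``.

    ``record`` may be a :class:`CODInput`, a mapping or a pandas row with the
    same field names.  An unclassifiable record (no gestational age and no
    birth weight below the sign levels of the hierarchy) yields
    ``("unknown", "unclassifiable")`` and a warning rather than an error.
    """
    if _flag(record, "major_congenital_anomaly"):
        return "congenital_anomaly", RULE_ANOMALY
    if any(_flag(record, s) for s in INFECTION_SIGNS):
        return "infection", RULE_INFECTION

    ga = record.get("ga_delivery_weeks") if isinstance(record, Mapping) else record.ga_delivery_weeks
    bw = record.get("birth_weight_g") if isinstance(record, Mapping) else record.birth_weight_g
    breathing = any(_flag(record, s) for s in BREATHING_SIGNS)
    complication = _flag(record, "maternal_pregnancy_complication")

    if _is_missing(ga) and _is_missing(bw):
        warnings.warn(
            "death record has neither gestational age nor birth weight; "
            "cause assigned as unknown",
            stacklevel=2,
        )
        return "unknown", RULE_UNCLASSIFIABLE

    # GA governs the band when present; weight is a fallback only
    if not _is_missing(ga):
        band = (
            "term"
            if ga >= TERM_GA_WEEKS
            else "moderate" if ga >= MODERATE_PRETERM_GA_WEEKS else "early"
        )
    else:
        band = (
            "term"
            if bw >= TERM_WEIGHT_G
            else "moderate" if bw >= MODERATE_PRETERM_WEIGHT_G else "early"
        )

    if band == "term":
        if breathing:
            return "asphyxia", RULE_TERM_ASPHYXIA
        return "unknown", RULE_TERM_UNKNOWN
    if band == "moderate":
        if breathing or complication:
            return "asphyxia", RULE_BAND_ASPHYXIA
        # preterm death with nothing else implicated
        return "prematurity", RULE_BAND_RESIDUAL
    return "prematurity", RULE_EARLY_PRETERM


class CauseOfDeathClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based neonatal cause-of-death classifier (scikit-learn style).

    The decision rules are fixed by the hierarchy above, so :meth:`fit` only
    records the class labels; :meth:`predict` maps a DataFrame of sign
    indicators to causes.  Exposed as an estimator so it composes with
    sklearn pipelines and so the rule engine and its audit trail share one
    object.
    """

    def fit(self, X=None, y=None):
        self.classes_ = np.asarray(CAUSE_LEVELS, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_with_rule(X)[0]

    def predict_with_rule(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(causes, rule_codes)`` for each row of ``X``."""
        if not hasattr(self, "classes_"):
            self.fit()
        causes = np.empty(len(X), dtype=object)
        rules = np.empty(len(X), dtype=object)
        for i, (_, row) in enumerate(X.iterrows()):
            causes[i], rules[i] = assign_cause(row.to_dict())
        return causes, rules


def classify_deaths(death_records: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every death record; never drops a row.

    Returns the input with appended ``cause`` and ``rule`` columns, plus a
    tally by cause (indexed by the five causes, summing to the record count).
    """
    clf = CauseOfDeathClassifier().fit()
    causes, rules = clf.predict_with_rule(death_records)
    out = death_records.copy()
    out["cause"] = causes
    out["rule"] = rules
    tally = (
        pd.Series(causes, dtype=object)
        .value_counts()
        .reindex(CAUSE_LEVELS, fill_value=0)
        .rename("n")
    )
    tally.index.name = "cause"
    return out, tally
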