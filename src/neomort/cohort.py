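"""Analysis-cohort construction: the enrollment exclusion cascade.

Screened pregnancies enter the live-birth analysis cohort after excluding,
in order: mothers not resident in a study cluster, mothers who died before
delivery, and births that ended in miscarriage, medical termination of
pregnancy, or stillbirth.  Multiples each contribute a separate infant row
sharing the maternal covariates.  The cascade is fully accounted: excluded
rows per reason plus retained live births equal the input infant rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .schema import validate_infant, validate_maternal

EXCLUSION_REASONS = [
    "non_resident",
    "maternal_death_before_delivery",
    "miscarriage",
    "medical_termination",
    "stillbirth",
]


class CohortError(ValueError):
    """Referential-integrity failure while building the cohort."""


@dataclass
class AnalysisCohort:
    """Live-birth analysis rows plus the exclusion ledger.

    ``data`` holds one row per retained live birth with maternal covariates
    joined on.  ``ledger`` counts excluded infant rows by reason, so that
    ``sum(ledger.values()) + live_births == screened_infants``.
    """

    data: pd.DataFrame
    ledger: dict = field(default_factory=dict)
    screened_mothers: int = 0
    screened_infants: int = 0

    @property
    def live_births(self) -> int:
        return len(self.data)

    @property
    def neonatal_deaths(self) -> int:
        return int((self.data["alive_at_28d"] == False).sum())  # noqa: E712

    def conserves_counts(self) -> bool:
        return sum(self.ledger.values()) + self.live_births == self.screened_infants


def build_cohort(
    maternal: pd.DataFrame, infants: pd.DataFrame, validate: bool = True
) -> AnalysisCohort:
    """Apply the exclusion cascade and join maternal covariates onto live births.

    Raises :class:`CohortError` for an infant referencing an unknown
    ``mother_id`` or a duplicate ``infant_id``.  Idempotent and independent
    of input row order (output rows are sorted by ``infant_id``).
    """
    if validate:
        validate_maternal(maternal)
        validate_infant(infants)
    else:
        if maternal["mother_id"].duplicated().any():
            raise CohortError("duplicate mother_id in maternal table")
    if infants["infant_id"].duplicated().any():
        dup = infants.loc[infants["infant_id"].duplicated(), "infant_id"].iloc[0]
        raise CohortError(f"duplicate infant_id {dup!r}")
    unknown = ~infants["mother_id"].isin(maternal["mother_id"])
    if unknown.any():
        bad = infants.loc[unknown, "mother_id"].iloc[0]
        raise CohortError(f"infant references unknown mother_id {bad!r}")

    merged = infants.merge(
        maternal, on="mother_id", how="left", suffixes=("", "_maternal")
    )

    ledger = {r: 0 for r in EXCLUSION_REASONS}
    keep = pd.Series(True, index=merged.index)

    def _exclude(mask: pd.Series, reason: str) -> None:
        hit = keep & mask.fillna(False)
        ledger[reason] = int(hit.sum())
        keep[hit] = False

    _exclude(merged["resident_in_cluster"] == False, "non_resident")  # noqa: E712
    _exclude(merged["died_before_delivery"] == True, "maternal_death_before_delivery")  # noqa: E712
    _exclude(merged["birth_outcome"] == "miscarriage", "miscarriage")
    _exclude(merged["birth_outcome"] == "medical_termination", "medical_termination")
    _exclude(merged["birth_outcome"] == "stillbirth", "stillbirth")

    data = (
        merged[keep]
        .sort_values("infant_id", kind="mergesort")
        .reset_index(drop=True)
    )
    assert (data["birth_outcome"] == "live_birth").all()
    return AnalysisCohort(
        data=data,
        ledger=ledger,
        screened_mothers=len(maternal),
        screened_infants=len(infants),
    )


def cod_analysis_set(cohort: AnalysisCohort) -> tuple[pd.DataFrame, int]:
    """Deaths eligible for cause assignment: those with a completed form.

    Returns ``(death_rows, n_dropped_missing_form)``.
    """
    deaths = cohort.data[cohort.data["alive_at_28d"] == False]  # noqa: E712
    with_form = deaths[deaths["cod_form_available"] == True]  # noqa: E712
    return with_form.reset_index(drop=True), len(deaths) - len(with_form)
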