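"""Descriptive outputs: mortality rates, cause distributions, status tables.

Rates are neonatal deaths (within 28 days of life) per 1,000 live births.
Percentages and rates are carried at full precision and rounded half-up to
one decimal only for display, matching how surveillance tables are printed.
Categorical breakdowns use per-variable complete-case denominators: rows
missing the variable are dropped from that table only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Union

import pandas as pd

from .cohort import AnalysisCohort
from .schema import CAUSE_LEVELS, INFANT_ENUMS, MATERNAL_ENUMS
from .variables import BIRTH_WEIGHT_BAND_LEVELS, add_derived


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.45 -> 2.5), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RateSummary:
    """Deaths per 1,000 live births within one stratum."""

    stratum: str
    deaths: int
    live_births: int

    @property
    def rate_per_1000(self) -> Optional[float]:
        if self.live_births == 0:
            return None
        return 1000.0 * self.deaths / self.live_births

    @property
    def rate_rounded(self) -> Optional[float]:
        r = self.rate_per_1000
        return None if r is None else round_half_up(r, 1)


def _as_frame(cohort: Union[AnalysisCohort, pd.DataFrame]) -> pd.DataFrame:
    return cohort.data if isinstance(cohort, AnalysisCohort) else cohort


def neonatal_mortality_rate(
    cohort: Union[AnalysisCohort, pd.DataFrame], stratify_by_year: bool = False
) -> list[RateSummary]:
    """Overall neonatal mortality rate, plus one per delivery year if asked."""
    df = _as_frame(cohort)
    died = (df["alive_at_28d"] == False) if len(df) else pd.Series(dtype=bool)  # noqa: E712
    out = [RateSummary("overall", int(died.sum()), len(df))]
    if out[0].live_births == 0:
        warnings.warn("zero live births: mortality rate undefined", stacklevel=2)
    if stratify_by_year and len(df):
        for year, grp in df.groupby("delivery_year", sort=True):
            n_died = int((grp["alive_at_28d"] == False).sum())  # noqa: E712
            out.append(RateSummary(str(year), n_died, len(grp)))
    return out


def rates_frame(summaries: list[RateSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": [s.stratum for s in summaries],
            "deaths": [s.deaths for s in summaries],
            "live_births": [s.live_births for s in summaries],
            "rate_per_1000": [s.rate_rounded for s in summaries],
        }
    )


def cause_distribution(
    causes: Union[pd.Series, pd.DataFrame], stratify_by_year: bool = False
) -> pd.DataFrame:
    """Per-cause counts and percentages of classified deaths.

    ``causes`` is either a Series of cause labels or a classified-deaths
    frame with a ``cause`` column (and ``delivery_year`` for stratification).
    Percentages are of the classified-death total and sum to 100 before
    rounding.
    """
    if isinstance(causes, pd.Series):
        frame = causes.to_frame("cause")
    else:
        frame = causes
    if frame.empty:
        return pd.DataFrame(columns=["stratum", "cause", "n", "pct"])

    def _one(label: str, sub: pd.DataFrame) -> pd.DataFrame:
        tally = (
            sub["cause"].value_counts().reindex(CAUSE_LEVELS, fill_value=0).astype(int)
        )
        total = int(tally.sum())
        return pd.DataFrame(
            {
                "stratum": label,
                "cause": tally.index,
                "n": tally.to_numpy(),
                "pct": [round_half_up(100.0 * n / total, 1) for n in tally],
            }
        )

    parts = [_one("overall", frame)]
    if stratify_by_year:
        for year, grp in frame.groupby("delivery_year", sort=True):
            parts.append(_one(str(year), grp))
    return pd.concat(parts, ignore_index=True)


def categorical_table(
    cohort: Union[AnalysisCohort, pd.DataFrame], variable: str
) -> pd.DataFrame:
    """Level counts and within-status percentages for one schema variable.

    Statuses are ``died`` (death before day 28) and ``alive``.  Percentages
    are computed among rows non-missing for the variable; the per-status
    complete-case denominator is included on every row.
    """
    valid = {
        **MATERNAL_ENUMS,
        **INFANT_ENUMS,
        "birth_weight_band": BIRTH_WEIGHT_BAND_LEVELS,
    }
    if variable not in valid:
        raise KeyError(
            f"unknown variable {variable!r}; valid names: {sorted(valid)}"
        )
    df = _as_frame(cohort)
    if variable not in df.columns and variable == "birth_weight_band":
        df = add_derived(df)
    levels = valid[variable]
    rows = []
    for status, mask in [
        ("died", df["alive_at_28d"] == False),  # noqa: E712
        ("alive", df["alive_at_28d"] == True),  # noqa: E712
    ]:
        sub = df.loc[mask, variable].dropna()
        denom = len(sub)
        counts = sub.value_counts()
        for level in levels:
            n = int(counts.get(level, 0))
            rows.append(
                {
                    "variable": variable,
                    "status": status,
                    "level": level,
                    "n": n,
                    "denominator": denom,
                    "pct": round_half_up(100.0 * n / denom, 1) if denom else None,
                }
            )
    return pd.DataFrame(rows)
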