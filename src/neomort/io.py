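"""CSV readers/writers for the registry schema, and the full pipeline.

Files are UTF-8 CSV with a fixed header per table (schema v1.0); flags are
written ``1``/``0`` and missing values as empty fields, so a write/read
round trip reproduces the in-memory tables exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import schema
from .cohort import AnalysisCohort, build_cohort, cod_analysis_set
from .cod import classify_deaths
from .descriptive import categorical_table, cause_distribution, neonatal_mortality_rate, rates_frame
from .predictive import ForwardQICSelector
from .risk import crude_rr, ClusterRelativeRisk, RiskModelError, two_by_two
from .simulate import SimulationConfig, generate_registry, summarize_truth
from .variables import get_spec

logger = logging.getLogger("neomort")

_FLAG_COLUMNS = set(schema.MATERNAL_FLAGS) | set(schema.INFANT_FLAGS) | set(schema.COD_FLAGS)
_FLOAT1_COLUMNS = {"ga_delivery_weeks"}
_FLOAT0_COLUMNS = {"birth_weight_g"}
_INT_COLUMNS = {"delivery_year", "age_at_death_days"}

#: default one-at-a-time risk factor list for the `risks` stage
DEFAULT_RISK_VARIABLES = [
    "age_category",
    "education",
    "bmi_category",
    "parity_category",
    "anc_visits_category",
    "ga_at_enrollment_category",
    "birth_weight_band",
    "preterm",
    "multiple_gestation",
]


def _format_cell(col: str, v) -> str:
    if pd.isna(v):
        return ""
    if col in _FLAG_COLUMNS:
        return "1" if bool(v) else "0"
    if col in _FLOAT1_COLUMNS:
        return f"{float(v):.1f}"
    if col in _FLOAT0_COLUMNS:
        return f"{float(v):.0f}"
    if col in _INT_COLUMNS:
        return str(int(v))
    return str(v)


def write_table(df: pd.DataFrame, path) -> None:
    """Write one registry table with canonical cell formatting."""
    out = pd.DataFrame(
        {c: [_format_cell(c, v) for v in df[c]] for c in df.columns}
    )
    out.to_csv(path, index=False, lineterminator="\n")


def write_registry(maternal, infants, cod, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "maternal": out_dir / "maternal.csv",
        "infant": out_dir / "infant.csv",
        "cod": out_dir / "cod.csv",
    }
    write_table(maternal, paths["maternal"])
    write_table(infants, paths["infant"])
    write_table(cod, paths["cod"])
    return paths


def _decode(df: pd.DataFrame, table: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        s = df[col].replace("", pd.NA)
        if col in _FLAG_COLUMNS:
            out[col] = s.map({"1": True, "0": False}).astype("boolean")
        elif col in _FLOAT1_COLUMNS | _FLOAT0_COLUMNS:
            out[col] = pd.to_numeric(s, errors="raise").astype("Float64")
        elif col == "delivery_year":
            out[col] = pd.to_numeric(s, errors="raise").astype("int64")
        elif col == "age_at_death_days":
            out[col] = pd.to_numeric(s, errors="raise").astype("Int64")
        else:
            out[col] = s
    return pd.DataFrame(out)


def read_tables(
    maternal_path,
    infant_path,
    cod_path=None,
    schema_version: schema.SchemaVersion = schema.DEFAULT_SCHEMA,
):
    """Read and validate the registry tables.

    Returns ``(maternal, infants, cod, report)`` where ``report`` counts
    missing values per column.  Raises :class:`schema.SchemaError` on a
    header mismatch or an out-of-dictionary categorical value (naming row,
    column and value).
    """
    raw_m = pd.read_csv(maternal_path, dtype=str, keep_default_na=False)
    schema.check_header(raw_m.columns, "maternal", schema_version)
    maternal = _decode(raw_m, "maternal")
    schema.validate_maternal(maternal, schema_version)

    raw_i = pd.read_csv(infant_path, dtype=str, keep_default_na=False)
    schema.check_header(raw_i.columns, "infant", schema_version)
    infants = _decode(raw_i, "infant")
    schema.validate_infant(infants, schema_version)

    cod = None
    if cod_path is not None:
        raw_c = pd.read_csv(cod_path, dtype=str, keep_default_na=False)
        schema.check_header(raw_c.columns, "cod", schema_version)
        cod = _decode(raw_c, "cod")
        schema.validate_cod(cod, schema_version)

    report = {
        "maternal_missing": {c: int(maternal[c].isna().sum()) for c in maternal},
        "infant_missing": {c: int(infants[c].isna().sum()) for c in infants},
        "rows": {
            "maternal": len(maternal),
            "infant": len(infants),
            "cod": 0 if cod is None else len(cod),
        },
    }
    return maternal, infants, cod, report


def _round_floats(obj, ndigits=8):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def _estimates_rows(estimates, variable, overall_p=None):
    rows = []
    for e in estimates:
        rows.append(
            {
                "variable": variable,
                "term": e.label,
                "reference": e.reference,
                "rr": e.rr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "method": e.method,
                "n": e.n,
                "overall_wald_p": overall_p,
            }
        )
    return rows


def risk_table(
    cohort: Union[AnalysisCohort, pd.DataFrame],
    variables: Optional[list] = None,
    crude: bool = True,
    cluster: bool = True,
    working_correlation: str = "independence",
) -> pd.DataFrame:
    """Tidy one-variable-at-a-time relative-risk table (crude and/or GEE)."""
    variables = DEFAULT_RISK_VARIABLES if variables is None else variables
    rows = []
    for var in variables:
        spec = get_spec(var)
        if crude and spec.kind == "categorical":
            for level in spec.levels:
                if level == spec.reference:
                    continue
                try:
                    est = crude_rr(
                        two_by_two(cohort, var, level, spec.reference),
                        label=f"{var}[{level}]",
                        reference=spec.reference,
                    )
                except ValueError as exc:  # empty exposure group at this scale
                    logger.warning("skipping crude %s[%s]: %s", var, level, exc)
                    continue
                rows.extend(_estimates_rows([est], var))
        if cluster:
            try:
                fit = ClusterRelativeRisk(
                    exposure=var, working_correlation=working_correlation
                ).fit(cohort)
                rows.extend(
                    _estimates_rows(fit.estimates_, var, fit.overall_wald_p_)
                )
            except RiskModelError as exc:
                logger.warning("skipping cluster fit for %s: %s", var, exc)
    return pd.DataFrame(rows)


def run_pipeline(
    out_dir,
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    input_paths: Optional[dict] = None,
    risk_variables: Optional[list] = None,
    candidates: Optional[list] = None,
) -> dict:
    """simulate (or load) -> cohort -> classify -> describe -> risks -> predict.

    Writes every intermediate CSV plus ``summary.json`` under ``out_dir`` and
    returns the summary dict.  Each stage logs its record counts; a stage
    failure aborts with the stage name while earlier outputs persist.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed}
    stage = "simulate"
    try:
        if input_paths is None:
            maternal, infants, cod, truth = generate_registry(
                config or SimulationConfig(), seed=seed
            )
            write_registry(maternal, infants, cod, out_dir)
            write_json(summarize_truth(truth), out_dir / "truth.json")
            summary["truth"] = summarize_truth(truth)
        else:
            maternal, infants, cod, _ = read_tables(
                input_paths["maternal"], input_paths["infant"], input_paths.get("cod")
            )
        logger.info("%s: %d pregnancies, %d infants", stage, len(maternal), len(infants))

        stage = "cohort"
        cohort = build_cohort(maternal, infants)
        write_table(cohort.data, out_dir / "cohort.csv")
        write_json(
            {
                "ledger": cohort.ledger,
                "screened_mothers": cohort.screened_mothers,
                "screened_infants": cohort.screened_infants,
                "live_births": cohort.live_births,
                "neonatal_deaths": cohort.neonatal_deaths,
            },
            out_dir / "exclusion_ledger.json",
        )
        summary["cohort"] = {
            "live_births": cohort.live_births,
            "neonatal_deaths": cohort.neonatal_deaths,
            "ledger": cohort.ledger,
        }
        logger.info("%s: %d live births, %d deaths", stage, cohort.live_births, cohort.neonatal_deaths)

        stage = "classify-cod"
        deaths, dropped = cod_analysis_set(cohort)
        if cod is not None and len(deaths):
            cod_rows = deaths[["infant_id", "delivery_year"]].merge(
                cod, on="infant_id", how="inner"
            )
        else:
            cod_rows = pd.DataFrame(columns=["infant_id", "delivery_year", *schema.COD_COLUMNS[1:]])
        classified, tally = classify_deaths(cod_rows)
        classified.to_csv(out_dir / "cod_classified.csv", index=False, lineterminator="\n")
        summary["cod"] = {
            "analysed_deaths": len(classified),
            "dropped_missing_form": dropped,
            "tally": {k: int(v) for k, v in tally.items()},
        }
        logger.info("%s: %d deaths classified, %d dropped", stage, len(classified), dropped)

        stage = "describe"
        rates = rates_frame(neonatal_mortality_rate(cohort, stratify_by_year=True))
        rates.to_csv(out_dir / "rates.csv", index=False, lineterminator="\n")
        dist = cause_distribution(classified, stratify_by_year=len(classified) > 0)
        dist.to_csv(out_dir / "cause_distribution.csv", index=False, lineterminator="\n")
        tables = pd.concat(
            [categorical_table(cohort, v) for v in ("delivery_attendant", "delivery_location")],
            ignore_index=True,
        )
        tables.to_csv(out_dir / "status_tables.csv", index=False, lineterminator="\n")
        summary["rates"] = rates.to_dict(orient="records")
        summary["cause_distribution"] = dist.to_dict(orient="records")

        stage = "risks"
        risks = risk_table(cohort, variables=risk_variables)
        risks.to_csv(out_dir / "risks.csv", index=False, lineterminator="\n")
        summary["risks"] = risks.to_dict(orient="records")

        stage = "predict"
        selector = ForwardQICSelector(candidates=candidates).fit(cohort)
        selector.path_.frame().to_csv(
            out_dir / "selection_path.csv", index=False, lineterminator="\n"
        )
        selector.summary_.frame().to_csv(
            out_dir / "final_model.csv", index=False, lineterminator="\n"
        )
        summary["predict"] = {
            "selected": selector.selected_,
            "marginal_r2": selector.summary_.marginal_r2,
            "qic": selector.summary_.qic,
            "final_model": selector.summary_.frame().to_dict(orient="records"),
        }
        logger.info("%s: selected %s", stage, selector.selected_)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_json(summary, out_dir / "summary.json")
    return summary
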