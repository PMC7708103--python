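"""Independently coded nested-if oracle for the cause-of-death hierarchy.

Deliberately structured as a flat transcription of the clinical narrative
(no banding helper, no shared code with the package) so it can serve as an
independent cross-check over an exhaustive factorial grid.
"""


def oracle_assign(rec: dict) -> str:
    if rec.get("major_congenital_anomaly"):
        return "congenital_anomaly"
    if (
        rec.get("tetanus")
        or rec.get("omphalitis")
        or rec.get("sepsis")
        or rec.get("pneumonia")
        or rec.get("infection_suspected")
    ):
        return "infection"
    ga = rec.get("ga_delivery_weeks")
    bw = rec.get("birth_weight_g")
    breathing = bool(rec.get("breathing_difficulty_at_birth")) or bool(
        rec.get("respiratory_distress")
    )
    complication = bool(rec.get("maternal_pregnancy_complication"))
    if ga is None and bw is None:
        return "unknown"
    if ga is not None:
        if ga >= 37.0:
            return "asphyxia" if breathing else "unknown"
        if ga >= 34.0:
            return "asphyxia" if (breathing or complication) else "prematurity"
        return "prematurity"
    if bw >= 2500.0:
        return "asphyxia" if breathing else "unknown"
    if bw >= 2000.0:
        return "asphyxia" if (breathing or complication) else "prematurity"
    return "prematurity"


FLAG_NAMES = [
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


def factorial_grid(ga_values, bw_values):
    """Every combination of the nine flags with the given GA/weight values."""
    for mask in range(2 ** len(FLAG_NAMES)):
        flags = {
            name: bool(mask >> j & 1) for j, name in enumerate(FLAG_NAMES)
        }
        for ga in ga_values:
            for bw in bw_values:
                rec = dict(flags)
                rec["ga_delivery_weeks"] = ga
                rec["birth_weight_g"] = bw
                yield rec
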