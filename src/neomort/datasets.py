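"""Published summary counts from the Belagavi (Karnataka, India) 2014-2018
rural population-based neonatal mortality surveillance cohort.

These are the printed enrollment-cascade and table cells of the study whose
marginal structure the synthetic generator emulates.  They serve as worked
inputs: expanded into row-level frames or 2x2 tables, they can be fed
through the descriptive and crude-risk code paths to reproduce the printed
rates, percentages and crude relative risks without any raw data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .risk import TwoByTwo
from .schema import (
    AGE_LEVELS,
    ANC_LEVELS,
    ATTENDANT_LEVELS,
    BMI_LEVELS,
    CAUSE_LEVELS,
    EDUCATION_LEVELS,
    GA_ENROLL_LEVELS,
    LOCATION_LEVELS,
    PARITY_LEVELS,
)
from .variables import BIRTH_WEIGHT_BAND_LEVELS

#: enrollment cascade (screened pregnancies through analysis deaths)
ENROLLMENT = {
    "screened": 47614,
    "non_resident": 8578,
    "maternal_death_before_delivery": 11,
    "miscarriage": 4929,
    "medical_termination": 2542,
    "stillbirth": 884,
    "women_included": 30657,
    "live_births": 30944,
    "neonatal_deaths": 758,
    "missing_cod_form": 8,
    "cod_analysis_deaths": 750,
}

LIVE_BIRTHS_BY_YEAR = {2014: 6789, 2015: 6623, 2016: 6219, 2017: 5774, 2018: 5539}
DEATHS_BY_YEAR = {2014: 194, 2015: 167, 2016: 153, 2017: 151, 2018: 93}

#: classified deaths per cause, by year and overall (order: congenital
#: anomaly, infection, prematurity, asphyxia, unknown)
CAUSE_COUNTS = {
    2014: [39, 65, 36, 44, 9],
    2015: [31, 45, 44, 41, 6],
    2016: [25, 25, 57, 40, 5],
    2017: [31, 29, 41, 37, 11],
    2018: [12, 14, 31, 26, 6],
    "overall": [138, 178, 209, 188, 37],
}

#: per-variable (died counts, alive counts) aligned with the schema levels
STATUS_TABLES = {
    "delivery_attendant": (
        ATTENDANT_LEVELS,
        [428, 95, 189, 4, 26, 14, 1],
        [15192, 3212, 10996, 102, 589, 81, 9],
    ),
    "delivery_location": (
        LOCATION_LEVELS,
        [568, 133, 39, 17],
        [21607, 7485, 753, 337],
    ),
    "age_category": (AGE_LEVELS, [104, 487, 145, 22], [3842, 20299, 5309, 735]),
    "education": (EDUCATION_LEVELS, [126, 580, 52], [3555, 23434, 3194]),
    "bmi_category": (BMI_LEVELS, [250, 447, 59], [10406, 17633, 2126]),
    "parity_category": (PARITY_LEVELS, [329, 360, 69], [11585, 16561, 2037]),
    "anc_visits_category": (ANC_LEVELS, [21, 108, 218, 411], [127, 914, 6152, 22990]),
    "ga_at_enrollment_category": (
        GA_ENROLL_LEVELS,
        [283, 247, 177, 49],
        [10892, 11006, 6422, 1771],
    ),
    "birth_weight_band": (
        BIRTH_WEIGHT_BAND_LEVELS,
        [108, 112, 254, 276],
        [8, 130, 5872, 24174],
    ),
    "preterm": (["preterm", "term"], [364, 394], [2871, 27314]),
    "multiple": (["multiple", "singleton"], [75, 683], [497, 29688]),
}


def cause_labels(stratum="overall") -> pd.Series:
    """Cause labels expanded to one row per classified death."""
    counts = CAUSE_COUNTS[stratum]
    return pd.Series(np.repeat(CAUSE_LEVELS, counts), name="cause")


def expand_status_table(variable: str) -> pd.DataFrame:
    """Row-level frame (variable level + 28-day status) from printed counts."""
    levels, died, alive = STATUS_TABLES[variable]
    rows = []
    for level, n_died, n_alive in zip(levels, died, alive):
        rows.append(
            pd.DataFrame({variable: level, "alive_at_28d": [False] * n_died})
        )
        rows.append(pd.DataFrame({variable: level, "alive_at_28d": [True] * n_alive}))
    return pd.concat(rows, ignore_index=True)


def two_by_two_from_counts(variable: str, level: str, reference: str) -> TwoByTwo:
    """2x2 table of one printed exposure level against its reference."""
    levels, died, alive = STATUS_TABLES[variable]
    i, j = levels.index(level), levels.index(reference)
    return TwoByTwo(
        a=died[i], n1=died[i] + alive[i], c=died[j], n0=died[j] + alive[j]
    )
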