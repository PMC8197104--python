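"""Published reference values for the South Korean study region (2007-2016).

Climate normals are Korea Meteorological Administration monthly means for the
study decade; accident statistics are the published summary counts and PET
summary statistics of the national construction accident registry over the
same period.  They serve two roles: calibration targets / default parameters
for the synthetic registry generator, and direct inputs to the Monte Carlo
probability analysis (which needs only per-type PET means and standard
deviations, not event-level records).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MONTHS = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)

# Monthly climate normals for South Korea (study decade averages).
MONTHLY_TA = np.array(
    [-0.9, 1.6, 6.3, 12.2, 17.8, 21.6, 25.1, 25.4, 20.9, 15.0, 8.2, 1.3]
)
MONTHLY_WIND = np.array(
    [2.3, 2.4, 2.5, 2.5, 2.2, 2.0, 2.0, 1.9, 1.7, 1.9, 2.1, 2.3]
)
MONTHLY_RH = np.array(
    [60.8, 60.0, 59.2, 61.2, 63.7, 72.9, 81.0, 79.4, 76.5, 71.3, 67.5, 63.3]
)
# Published monthly mean PET for the region (context, not a generator target).
MONTHLY_PET = np.array(
    [-12.0, -8.9, -2.8, 4.9, 12.2, 16.9, 21.2, 21.6, 16.5, 9.3, 0.5, -9.1]
)

# The 18-category accident taxonomy used for all stratified analyses.
ACCIDENT_TYPES = (
    "electric shock",
    "slip",
    "fall",
    "traffic accident",
    "be hit",
    "collision",
    "get jammed",
    "leak or contact of chemicals",
    "fire",
    "bumped",
    "drowned",
    "explosion",
    "hypoxia",
    "violence",
    "contact of abnormal temperature",
    "cut",
    "animal injury",
    "fall beneath",
)

SEVERITIES = ("fatal", "injury")

# Published monthly accident counts per type over the study decade,
# {type: {"fatal": [Jan..Dec], "injury": [Jan..Dec]}}.  Used as the default
# seasonal-shape and base-rate calibration of the synthetic registry.
MONTHLY_COUNTS: dict[str, dict[str, list[int]]] = {
    "electric shock": {
        "fatal": [6, 13, 10, 8, 12, 19, 36, 57, 19, 14, 10, 11],
        "injury": [70, 80, 111, 113, 146, 161, 203, 203, 139, 145, 119, 111],
    },
    "slip": {
        "fatal": [12, 3, 8, 12, 10, 13, 11, 9, 6, 14, 12, 9],
        "injury": [2057, 1847, 2677, 2796, 3069, 3193, 2993, 3109, 2824, 3365, 3203, 2996],
    },
    "fall": {
        "fatal": [196, 177, 248, 230, 247, 223, 237, 245, 234, 286, 263, 218],
        "injury": [4250, 3784, 5674, 5990, 6464, 6499, 6218, 6751, 6126, 7355, 6641, 5266],
    },
    "traffic accident": {
        "fatal": [24, 24, 26, 26, 32, 30, 37, 41, 32, 35, 48, 37],
        "injury": [134, 111, 152, 152, 161, 160, 203, 180, 146, 164, 182, 223],
    },
    "be hit": {
        "fatal": [24, 24, 22, 36, 27, 31, 30, 34, 32, 36, 31, 23],
        "injury": [1428, 1310, 2060, 2491, 2757, 2896, 2812, 2850, 2545, 2921, 2547, 1959],
    },
    "collision": {
        "fatal": [26, 29, 25, 37, 43, 29, 41, 23, 37, 33, 31, 37],
        "injury": [187, 178, 321, 347, 354, 330, 375, 320, 318, 346, 364, 302],
    },
    "get jammed": {
        "fatal": [16, 10, 15, 23, 17, 26, 18, 8, 12, 12, 19, 17],
        "injury": [996, 967, 1507, 1731, 1845, 1831, 1570, 1685, 1549, 1926, 1826, 1488],
    },
    "leak or contact of chemicals": {
        "fatal": [4, 4, 4, 1, 6, 4, 3, 3, 7, 0, 3, 9],
        "injury": [28, 26, 31, 35, 45, 43, 63, 61, 41, 45, 39, 34],
    },
    "fire": {
        "fatal": [18, 1, 5, 5, 1, 5, 1, 7, 11, 4, 8, 4],
        "injury": [123, 60, 113, 46, 60, 70, 54, 60, 46, 43, 46, 92],
    },
    "bumped": {
        "fatal": [10, 15, 19, 29, 26, 26, 25, 18, 32, 35, 21, 36],
        "injury": [1000, 864, 1406, 1753, 1920, 2030, 1839, 1985, 1667, 2176, 1793, 1416],
    },
    "drowned": {
        "fatal": [5, 2, 6, 5, 7, 8, 16, 7, 8, 11, 3, 19],
        "injury": [1, 1, 0, 0, 1, 4, 2, 8, 1, 3, 2, 2],
    },
    "explosion": {
        "fatal": [27, 3, 8, 3, 3, 5, 14, 11, 2, 6, 0, 9],
        "injury": [70, 64, 93, 60, 65, 94, 82, 83, 59, 76, 95, 94],
    },
    "hypoxia": {
        "fatal": [0, 2, 3, 2, 4, 1, 8, 6, 6, 3, 4, 4],
        "injury": [2, 2, 4, 3, 3, 2, 2, 8, 1, 2, 0, 4],
    },
    "violence": {
        "fatal": [0, 0, 0, 3, 0, 1, 1, 0, 0, 0, 2, 0],
        "injury": [10, 12, 11, 12, 9, 11, 12, 7, 13, 12, 12, 6],
    },
    "contact of abnormal temperature": {
        "fatal": [0, 1, 0, 0, 1, 1, 5, 5, 1, 1, 1, 2],
        "injury": [95, 67, 75, 60, 62, 81, 113, 99, 61, 81, 71, 110],
    },
    "cut": {
        "fatal": [0, 0, 1, 1, 2, 1, 1, 2, 1, 2, 2, 0],
        "injury": [935, 852, 1327, 1515, 1758, 1957, 1939, 2062, 1791, 1946, 1688, 1301],
    },
    "animal injury": {
        "fatal": [0, 0, 0, 0, 0, 2, 3, 3, 4, 1, 0, 0],
        "injury": [0, 1, 1, 3, 8, 14, 20, 24, 17, 4, 2, 0],
    },
    "fall beneath": {
        "fatal": [10, 10, 17, 15, 17, 14, 13, 10, 14, 17, 16, 8],
        "injury": [297, 290, 461, 470, 531, 524, 504, 522, 442, 555, 467, 392],
    },
}

# Published PET summary statistics (deg C) per accident type for fatal
# accidents: the inputs of the Monte Carlo probability analysis.
FATAL_PET_PARAMS: dict[str, tuple[float, float]] = {
    "electric shock": (23.01, 13.60),
    "slip": (16.20, 13.92),
    "fall": (16.45, 13.71),
    "traffic accident": (13.97, 15.05),
    "be hit": (16.40, 13.85),
    "collision": (15.32, 13.52),
    "get jammed": (15.34, 14.49),
    "leak or contact of chemicals": (12.26, 15.49),
    "fire": (14.16, 15.35),
    "bumped": (15.74, 14.16),
    "drowned": (14.94, 13.18),
    "explosion": (12.67, 15.60),
    "hypoxia": (21.69, 13.99),
    "violence": (13.26, 7.18),
    "contact of abnormal temperature": (24.98, 17.96),
    "cut": (22.02, 11.67),
    "animal injury": (29.15, 5.57),
    "fall beneath": (17.08, 13.26),
}

# Worked example of the administrative record linkage: six accident records
# with their matched station-hour weather and the PET reported by the
# reference simulation tool used in the original analysis.
LINKAGE_EXAMPLE = pd.DataFrame(
    [
        ("Seoul", "Gangbuk-gu", "2009-01-02 09:00", -6.2, 5.3, 1.9, 64.0, -9.5, "fall"),
        ("Seoul", "Jung-gu", "2009-01-02 09:00", -6.2, 5.3, 1.9, 64.0, -9.5, "traffic accident"),
        ("Seoul", "Gangseo-gu", "2015-11-01 13:00", 0.9, 22.4, 4.7, 50.0, -2.5, "fall"),
        ("Seoul", "Gangseo-gu", "2015-11-01 15:00", 2.3, 20.3, 4.3, 41.0, -1.3, "be hit"),
        ("Cheongju", "Sangdang-gu", "2010-12-01 10:00", -1.0, 17.2, 4.5, 77.0, -5.0, "fall"),
        ("Incheon", "Nam-gu", "2010-12-01 10:00", -4.5, 12.4, 7.6, 57.0, -10.5, "fall beneath"),
    ],
    columns=["city", "district", "timestamp", "ta", "tmrt", "v", "rh",
             "pet_reported", "accident_type"],
)


def fatal_params_frame() -> pd.DataFrame:
    """Per-type PET mean/std for fatal accidents as a tidy frame."""
    rows = [
        {"accident_type": t, "severity": "fatal", "mean": m, "std": s}
        for t, (m, s) in FATAL_PET_PARAMS.items()
    ]
    return pd.DataFrame(rows)


def registry_totals() -> pd.DataFrame:
    """Decade totals per (type, severity) implied by the monthly counts."""
    rows = []
    for t in ACCIDENT_TYPES:
        for sev in SEVERITIES:
            rows.append(
                {"accident_type": t, "severity": sev,
                 "total": int(np.sum(MONTHLY_COUNTS[t][sev]))}
            )
    return pd.DataFrame(rows)
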