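"""Bundled six-subject reference cohort for the reporting stage.

Per-subject region values from the clinical study this pipeline emulates,
kept as regression fixtures: the summary-statistics and radiobiology stages
must reproduce the published cohort rows (mean, SD, COV, median, range) and
the femur BED column from these inputs.
"""

from __future__ import annotations

import pandas as pd

SUBJECTS = [
    "IGPC-02-026",
    "IGPC-02-028",
    "IGPC-02-029",
    "IGPC-02-031",
    "IGPC-02-032",
    "IGPC-02-033",
]

#: mean Logan distribution volume per region, mL/g
LDV_ML_PER_G = pd.DataFrame(
    {
        "tumor": [5.38, 2.78, 2.16, 2.72, 2.03, 2.77],
        "total_prostate": [1.73, 1.69, 1.19, 1.27, 1.56, 1.66],
        "normal_prostate": [1.56, 1.67, 1.17, 1.19, 1.54, 1.63],
        "femur_r": [0.26, 0.36, 0.32, 0.29, 0.30, 0.32],
        "femur_l": [0.26, 0.36, 0.32, 0.27, 0.31, 0.32],
    },
    index=SUBJECTS,
)

#: extrapolated arterial AUC per subject, Bq s/mL
AUC_CA_BQ_S_PER_ML = pd.Series(
    [1.50e8, 1.13e8, 2.00e8, 1.58e8, 1.38e8, 1.00e8], index=SUBJECTS, name="auc_ca"
)

#: mean absorbed dose per region for one 7.4 GBq cycle, Gy
DOSE_GY_PER_CYCLE = pd.DataFrame(
    {
        "tumor": [146.3, 57.2, 77.7, 77.4, 50.9, 50.6],
        "total_prostate": [48.0, 35.3, 44.1, 36.8, 39.4, 30.9],
        "normal_prostate": [43.3, 35.0, 43.5, 34.6, 38.9, 30.2],
        "femur_r": [6.7, 7.0, 11.0, 7.7, 7.1, 5.3],
        "femur_l": [6.7, 6.9, 10.9, 7.2, 7.4, 5.4],
    },
    index=SUBJECTS,
)

#: mean biologically effective dose per region for one cycle, Gy
BED_GY_PER_CYCLE = pd.DataFrame(
    {
        "tumor": [230.4, 68.4, 97.7, 99.1, 59.5, 59.1],
        "total_prostate": [59.2, 40.6, 50.9, 42.0, 44.7, 34.3],
        "normal_prostate": [51.0, 40.2, 50.1, 38.9, 44.1, 33.4],
        "femur_r": [6.8, 7.1, 11.4, 7.9, 7.3, 5.4],
        "femur_l": [6.9, 7.1, 11.3, 7.3, 7.6, 5.4],
    },
    index=SUBJECTS,
)

#: standard therapy cycle activity, GBq
CYCLE_ACTIVITY_GBQ = 7.4

#: diagnostic administered activity, GBq
DIAGNOSTIC_ACTIVITY_GBQ = 0.325
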