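"""Reported validation results of the 32 algorithms.

These are the 2x2 counts and printed test characteristics from the Ontario
chart-review validation study this package models: 2015 eligible patients
aged 65+ discharged from 20 EDs with a primary atrial-fibrillation
diagnosis, reference standard = chart documentation of an ED oral
anticoagulant prescription. Algorithms 1-16 use the full cohort (n = 2015);
17-32 repeat them after excluding the 65 patients with a VTE diagnosis in
the previous 5 years (n = 1950).

The counts are inputs (e.g. to the ``from-counts`` evaluation mode and the
full-table regression test); the printed metrics let callers compare a
recomputation against what was reported. Proportions were printed at 3
decimals, rates at 1.
"""

from __future__ import annotations

import pandas as pd

from oacphen.metrics import Counts2x2

TABLE1_N = 2015
TABLE2_N = 1950

SECTION_PLAIN = "Filled"
SECTION_GATE_ANY = (
    "Filled prior to any appointment with a family physician, cardiologist, or internist"
)
SECTION_GATE_ANY_NO_PRIOR = (
    SECTION_GATE_ANY + " and had no appointments 30 d prior to ED visit"
)
SECTION_GATE_OWN = (
    "Filled prior to any appointment with their family physician, cardiologist, or internist"
)

_SECTION_BY_POS = {**{i: SECTION_PLAIN for i in range(1, 12)},
                   12: SECTION_GATE_ANY, 13: SECTION_GATE_ANY, 14: SECTION_GATE_ANY,
                   15: SECTION_GATE_ANY_NO_PRIOR, 16: SECTION_GATE_OWN}

# (algo_id, window, tp, tn, fp, fn,
#  sens, sens_lo, sens_hi, spec, spec_lo, spec_hi,
#  ppv, ppv_lo, ppv_hi, npv, npv_lo, npv_hi, rate_percent)
_ROWS = [
    (1, "0", 198, 1576, 36, 205, 0.491, 0.442, 0.540, 0.978, 0.971, 0.985, 0.846, 0.800, 0.892, 0.885, 0.870, 0.900, 11.6),
    (2, "0-3", 335, 1466, 146, 68, 0.831, 0.794, 0.868, 0.909, 0.895, 0.923, 0.696, 0.655, 0.737, 0.956, 0.946, 0.966, 23.9),
    (3, "1-3", 137, 1502, 110, 266, 0.340, 0.294, 0.386, 0.932, 0.920, 0.944, 0.555, 0.493, 0.617, 0.850, 0.833, 0.867, 12.3),
    (4, "0-4", 338, 1441, 171, 65, 0.839, 0.803, 0.875, 0.894, 0.879, 0.909, 0.664, 0.623, 0.705, 0.957, 0.947, 0.967, 25.3),
    (5, "1-4", 140, 1477, 135, 263, 0.347, 0.301, 0.393, 0.916, 0.902, 0.930, 0.509, 0.450, 0.568, 0.849, 0.832, 0.866, 13.7),
    (6, "0-7", 346, 1374, 238, 57, 0.859, 0.825, 0.893, 0.852, 0.835, 0.869, 0.592, 0.552, 0.632, 0.960, 0.950, 0.970, 29.0),
    (7, "1-7", 148, 1410, 202, 255, 0.367, 0.320, 0.414, 0.875, 0.859, 0.891, 0.423, 0.371, 0.475, 0.847, 0.830, 0.864, 17.4),
    (8, "0-14", 350, 1297, 315, 53, 0.868, 0.835, 0.901, 0.805, 0.786, 0.824, 0.526, 0.488, 0.564, 0.961, 0.951, 0.971, 33.0),
    (9, "1-14", 152, 1333, 279, 251, 0.377, 0.330, 0.424, 0.827, 0.809, 0.845, 0.353, 0.308, 0.398, 0.842, 0.824, 0.860, 21.4),
    (10, "0-30", 356, 1189, 423, 47, 0.883, 0.852, 0.914, 0.738, 0.717, 0.759, 0.457, 0.422, 0.492, 0.962, 0.951, 0.973, 38.7),
    (11, "1-30", 158, 1225, 387, 245, 0.392, 0.344, 0.440, 0.760, 0.739, 0.781, 0.290, 0.252, 0.328, 0.833, 0.814, 0.852, 27.1),
    (12, "0-14", 264, 1560, 52, 139, 0.655, 0.609, 0.701, 0.968, 0.959, 0.977, 0.835, 0.794, 0.876, 0.918, 0.905, 0.931, 15.7),
    (13, "0-30", 272, 1557, 55, 131, 0.675, 0.629, 0.721, 0.966, 0.957, 0.975, 0.832, 0.791, 0.873, 0.922, 0.909, 0.935, 16.2),
    (14, "0-30", 272, 1557, 55, 131, 0.675, 0.629, 0.721, 0.966, 0.957, 0.975, 0.832, 0.791, 0.873, 0.922, 0.909, 0.935, 16.2),
    (15, "0-30", 98, 1597, 15, 305, 0.243, 0.201, 0.285, 0.991, 0.986, 0.996, 0.867, 0.804, 0.930, 0.840, 0.824, 0.856, 5.6),
    (16, "0-30", 236, 1567, 45, 167, 0.586, 0.538, 0.634, 0.972, 0.964, 0.980, 0.840, 0.797, 0.883, 0.904, 0.890, 0.918, 14.0),
    (17, "0", 194, 1524, 35, 197, 0.496, 0.446, 0.546, 0.978, 0.971, 0.985, 0.847, 0.800, 0.894, 0.886, 0.871, 0.901, 11.7),
    (18, "0-3", 325, 1418, 141, 66, 0.831, 0.794, 0.868, 0.910, 0.896, 0.924, 0.697, 0.655, 0.739, 0.956, 0.946, 0.966, 23.9),
    (19, "1-3", 131, 1453, 106, 260, 0.335, 0.288, 0.382, 0.932, 0.920, 0.944, 0.553, 0.490, 0.616, 0.848, 0.831, 0.865, 12.2),
    (20, "0-4", 328, 1394, 165, 63, 0.839, 0.803, 0.875, 0.894, 0.879, 0.909, 0.665, 0.623, 0.707, 0.957, 0.947, 0.967, 25.3),
    (21, "1-4", 134, 1429, 130, 257, 0.343, 0.296, 0.390, 0.917, 0.903, 0.931, 0.508, 0.448, 0.568, 0.848, 0.831, 0.865, 13.5),
    (22, "0-7", 336, 1329, 230, 55, 0.859, 0.825, 0.893, 0.852, 0.834, 0.870, 0.594, 0.554, 0.634, 0.960, 0.950, 0.970, 29.0),
    (23, "1-7", 142, 1364, 195, 249, 0.363, 0.315, 0.411, 0.875, 0.859, 0.891, 0.421, 0.368, 0.474, 0.846, 0.828, 0.864, 17.3),
    (24, "0-14", 340, 1255, 304, 51, 0.870, 0.837, 0.903, 0.805, 0.785, 0.825, 0.528, 0.489, 0.567, 0.961, 0.951, 0.971, 33.0),
    (25, "1-14", 146, 1290, 269, 245, 0.373, 0.325, 0.421, 0.827, 0.808, 0.846, 0.352, 0.306, 0.398, 0.840, 0.822, 0.858, 21.3),
    (26, "0-30", 346, 1150, 409, 45, 0.885, 0.853, 0.917, 0.738, 0.716, 0.760, 0.458, 0.422, 0.494, 0.962, 0.951, 0.973, 38.7),
    (27, "1-30", 152, 1185, 374, 239, 0.389, 0.341, 0.437, 0.760, 0.739, 0.781, 0.289, 0.250, 0.328, 0.832, 0.813, 0.851, 27.0),
    (28, "0-14", 257, 1508, 51, 134, 0.657, 0.610, 0.704, 0.967, 0.958, 0.976, 0.834, 0.792, 0.876, 0.918, 0.905, 0.931, 15.8),
    (29, "0-30", 265, 1505, 54, 126, 0.678, 0.632, 0.724, 0.965, 0.956, 0.974, 0.831, 0.790, 0.872, 0.923, 0.910, 0.936, 16.4),
    (30, "0-30", 265, 1505, 54, 126, 0.678, 0.632, 0.724, 0.965, 0.956, 0.974, 0.831, 0.790, 0.872, 0.923, 0.910, 0.936, 16.4),
    (31, "0-30", 95, 1544, 15, 296, 0.243, 0.200, 0.286, 0.990, 0.985, 0.995, 0.864, 0.800, 0.928, 0.839, 0.822, 0.856, 5.6),
    (32, "0-30", 229, 1515, 44, 162, 0.586, 0.537, 0.635, 0.972, 0.964, 0.980, 0.839, 0.795, 0.883, 0.903, 0.889, 0.917, 14.0),
]

_FIELDS = [
    "algo_id", "window", "tp", "tn", "fp", "fn",
    "sens", "sens_lo", "sens_hi", "spec", "spec_lo", "spec_hi",
    "ppv", "ppv_lo", "ppv_hi", "npv", "npv_lo", "npv_hi", "rate_percent",
]


def published_table() -> pd.DataFrame:
    """All 32 reported rows: counts, printed metrics and section heading."""
    df = pd.DataFrame(_ROWS, columns=_FIELDS)
    df["section"] = [
        _SECTION_BY_POS[(i - 1) % 16 + 1] for i in df["algo_id"]
    ]
    df["vte_exclusion"] = df["algo_id"] > 16
    return df


def published_counts(algo_id: int) -> Counts2x2:
    """The reported 2x2 counts for one algorithm."""
    row = _ROWS[algo_id - 1]
    assert row[0] == algo_id
    return Counts2x2(tp=row[2], tn=row[3], fp=row[4], fn=row[5])
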