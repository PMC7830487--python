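"""Reference summary tables for the mung bean sprouting study design.

These are the published per-time-point (mean, sd) summaries of the
conventional quality measurements (gravimetric water content, pH,
conductivity, titrated ascorbic acid), shipped as fixtures: the
summary-statistics entry points consume them directly, and the spectra
simulator anchors its trajectories to them. All determinations were done
in triplicate (n = 3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import GroupSummary

# germination_h: (water_pct mean, sd), (pH mean, sd), (conductivity uS/cm mean, sd)
QUALITY_SUMMARY = {
    0: ((47.94, 0.38), (6.41, 0.01), (837.0, 5.57)),
    6: ((55.61, 0.36), (6.43, 0.02), (851.0, 2.65)),
    12: ((56.54, 0.39), (6.41, 0.02), (899.0, 4.00)),
    18: ((59.62, 0.41), (6.30, 0.02), (910.0, 4.73)),
    24: ((61.61, 0.31), (6.37, 0.03), (947.0, 4.58)),
    30: ((63.86, 0.34), (6.25, 0.03), (992.0, 6.08)),
    36: ((64.50, 0.31), (6.13, 0.03), (831.0, 6.67)),
    42: ((64.76, 0.28), (6.17, 0.03), (1005.0, 7.00)),
    48: ((67.44, 0.39), (6.33, 0.01), (1030.0, 6.08)),
    54: ((69.01, 0.47), (6.07, 0.02), (981.0, 4.16)),
    60: ((70.86, 0.36), (6.03, 0.03), (1201.0, 6.67)),
    66: ((73.69, 0.36), (5.88, 0.03), (951.0, 4.16)),
    72: ((75.98, 0.39), (5.55, 0.03), (1139.0, 4.58)),
    78: ((78.14, 0.46), (5.55, 0.01), (1433.0, 4.36)),
    84: ((79.48, 0.31), (5.84, 0.03), (1251.0, 5.20)),
    90: ((80.67, 0.37), (5.22, 0.01), (1131.0, 6.51)),
    96: ((81.15, 0.33), (5.34, 0.03), (1514.0, 6.43)),
    102: ((82.33, 0.44), (5.19, 0.03), (1157.0, 3.06)),
    108: ((83.80, 0.46), (5.19, 0.03), (1302.0, 6.51)),
    114: ((83.95, 0.33), (5.07, 0.03), (1492.0, 6.03)),
    120: ((85.24, 0.44), (5.06, 0.03), (1354.0, 1.73)),
}

# germination_h: (titration mg/100 g mean, sd) for ascorbic acid
ASCORBIC_TITRATION_SUMMARY = {
    0: (7.31, 0.34),
    24: (11.32, 0.43),
    48: (12.86, 0.61),
    72: (16.74, 0.60),
    96: (21.44, 0.69),
    120: (30.58, 2.39),
}

N_PER_CELL = 3


def quality_groups(variable: str) -> list[GroupSummary]:
    """GroupSummary list for 'water_pct', 'ph' or 'conductivity',
    ordered by germination time."""
    col = {"water_pct": 0, "ph": 1, "conductivity": 2}
    if variable not in col:
        raise KeyError(f"unknown quality variable {variable!r}")
    j = col[variable]
    return [
        GroupSummary(t, QUALITY_SUMMARY[t][j][0], QUALITY_SUMMARY[t][j][1], N_PER_CELL)
        for t in sorted(QUALITY_SUMMARY)
    ]


def ascorbic_groups() -> list[GroupSummary]:
    return [
        GroupSummary(t, m, s, N_PER_CELL)
        for t, (m, s) in sorted(ASCORBIC_TITRATION_SUMMARY.items())
    ]


def water_pct_trajectory(times) -> np.ndarray:
    """Mean water content (%) linearly interpolated at arbitrary hours."""
    ts = np.array(sorted(QUALITY_SUMMARY))
    ws = np.array([QUALITY_SUMMARY[t][0][0] for t in ts])
    return np.interp(np.asarray(times, dtype=float), ts, ws)


def ascorbic_trajectory_mg_per_100g(times) -> np.ndarray:
    """Mean titrated ascorbic acid (mg/100 g) linearly interpolated at
    arbitrary hours."""
    ts = np.array(sorted(ASCORBIC_TITRATION_SUMMARY))
    cs = np.array([ASCORBIC_TITRATION_SUMMARY[t][0] for t in ts])
    return np.interp(np.asarray(times, dtype=float), ts, cs)


def quality_summary_frame() -> pd.DataFrame:
    rows = []
    for t in sorted(QUALITY_SUMMARY):
        (wm, ws), (pm, ps), (cm, cs) = QUALITY_SUMMARY[t]
        rows.append(
            {
                "germination_h": t,
                "water_pct_mean": wm,
                "water_pct_sd": ws,
                "ph_mean": pm,
                "ph_sd": ps,
                "conductivity_mean": cm,
                "conductivity_sd": cs,
            }
        )
    return pd.DataFrame(rows)
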