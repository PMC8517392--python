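"""Published reference summaries for the default cohort calibration.

Group-level summary statistics of a published 50-vs-50 normal-control /
type-2-diabetes myocardial-work comparison.  The synthetic generator's
default distributions are parameterized from these rows, and the
statistics layer can recompute the published test statistics directly
from them (summary statistics are sufficient for the pooled t-test and
the chi-square test).  Values are data, not code: means and SDs for
normally summarized rows, medians and IQRs for skewed rows, counts for
categorical rows.
"""

from __future__ import annotations

__all__ = [
    "GROUP_SIZES",
    "MEAN_SD_ROWS",
    "MEDIAN_IQR_ROWS",
    "COUNT_ROWS",
    "AGREEMENT_ROWS",
]

#: (n control, n diabetes)
GROUP_SIZES: tuple[int, int] = (50, 50)

#: variable -> ((mean, sd) control, (mean, sd) diabetes)
MEAN_SD_ROWS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "age_yr": ((46.88, 10.60), (50.20, 9.73)),
    "bmi_kg_m2": ((24.32, 3.67), (26.09, 3.80)),
    "bsa_m2": ((1.72, 0.16), (1.83, 0.24)),
    "sbp_mmhg": ((118.84, 3.94), (120.68, 6.00)),
    "dbp_mmhg": ((77.70, 6.31), (79.24, 7.40)),
    "pulse_pressure_mmhg": ((41.14, 7.13), (41.44, 8.85)),
    "heart_rate_bpm": ((67.82, 8.37), (71.02, 9.41)),
    "tc_mmol_l": ((4.33, 0.61), (4.50, 1.01)),
    "tg_mmol_l": ((1.65, 0.64), (2.17, 1.04)),
    "ldl_mmol_l": ((2.48, 0.70), (2.79, 0.66)),
    "hba1c_pct": ((5.24, 0.36), (8.06, 1.37)),
    "lad_mm": ((33.38, 3.46), (34.62, 3.45)),
    "lvdd_mm": ((45.76, 2.62), (45.54, 2.11)),
    "lvedv_ml": ((98.00, 12.58), (96.80, 10.68)),
    "gwi_mmhg_pct": ((1899.84, 173.47), (1712.80, 249.44)),
    "gcw_mmhg_pct": ((2151.08, 196.17), (1934.58, 266.64)),
}

#: variable -> ((median, iqr) control, (median, iqr) diabetes)
MEDIAN_IQR_ROWS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "hdl_mmol_l": ((1.01, 0.30), (1.03, 0.23)),
    "lvef_pct": ((63.50, 3.25), (62.00, 4.00)),
    "gls_pct": ((-19.50, 3.00), (-17.00, 3.00)),
    "gww_mmhg_pct": ((34.50, 26.50), (45.00, 38.50)),
    "gwe_pct": ((98.00, 1.00), (97.00, 2.00)),
}

#: variable -> (positives control, positives diabetes); group sizes apply
COUNT_ROWS: dict[str, tuple[int, int]] = {
    "male": (29, 26),
    "smoking": (12, 14),
}

#: observer-agreement rows: parameter -> (mean measurement 1, mean measurement 2)
AGREEMENT_ROWS: dict[str, tuple[float, float]] = {
    "gww_intraobserver": (36.65, 39.90),
    "gwi_intraobserver": (1784.70, 1797.40),
    "gcw_intraobserver": (1965.95, 2009.05),
    "gwe_intraobserver": (97.40, 97.45),
}
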