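"""Published study values used as computational inputs.

These are the printed per-stratum counts and diagnostic rates from the
source cohort (n = 235; 68 recurrent, 167 non-recurrent). They are inputs
to the reproduction harness — everything derived from them (odds ratios,
confidence intervals, predictive values, chi-square p-values) is recomputed
by this package at run time, never copied.
"""

from __future__ import annotations

N_RECURRENT = 68
N_NON_RECURRENT = 167
N_TOTAL = N_RECURRENT + N_NON_RECURRENT

#: FIGO stage counts per stratum (stages I-IV)
STAGE_COUNTS = {
    "non_recurrent": {1: 122, 2: 18, 3: 23, 4: 4},
    "recurrent": {1: 13, 2: 9, 3: 28, 4: 18},
}

#: parity 2x2 counts: rows (nulliparous, parous), columns (non-recurrent, recurrent)
PARITY_TABLE = ((61, 14), (104, 52))

#: printed cutoff-table rows: (auc, auc_p, cutoff, sensitivity, specificity, ppv, npv)
CUTOFF_TABLE = {
    "age": (0.591, 0.029, 55.0, 0.676, 0.491, 35.11, 78.85),
    "ca125_pre": (0.672, 0.005, 124.5, 0.672, 0.618, 41.67, 82.26),
    "crp_pre": (0.619, 0.004, 0.26, 0.691, 0.575, 39.83, 82.05),
    "ddimer_pre": (0.619, 0.007, 1.1, 0.803, 0.467, 40.50, 84.00),
    "wbc_post": (0.592, 0.028, 57.00, 0.582, 0.588, 36.44, 77.60),
    "crp_post": (0.603, 0.016, 0.08, 0.875, 0.342, 34.56, 87.30),
    "albumin_post": (0.621, 0.010, 4.0, 0.655, 0.532, 38.29, 77.64),
    "wbc_diff": (0.594, 0.025, -29.00, 0.896, 0.321, 34.26, 88.88),
}

#: printed univariate odds ratios for recurrence: (OR, ci_low, ci_high)
UNIVARIATE_RECURRENCE = {
    "age": (2.01, 1.11, 3.64),
    "figo_advanced": (10.84, 5.63, 20.85),
    "ca125_pre": (3.31, 1.82, 6.02),
    "crp_pre": (3.02, 1.66, 5.50),
    "ddimer_pre": (3.57, 1.74, 7.31),
    "wbc_post": (1.98, 1.11, 3.53),
    "crp_post": (3.63, 1.61, 8.15),
    "albumin_post": (2.15, 1.11, 4.16),
    "wbc_diff": (4.17, 1.69, 10.29),
    "ppsp_high": (8.74, 4.03, 18.96),
}

#: printed parity comparison p-value
PARITY_P = 0.021

#: printed recurrence percentage
RECURRENCE_PCT = 28.9


def figo_recurrence_table():
    """2x2 counts: FIGO III/IV (exposed) vs I/II against recurrence."""
    rec = STAGE_COUNTS["recurrent"]
    non = STAGE_COUNTS["non_recurrent"]
    return (
        rec[3] + rec[4],       # a: advanced stage, recurrent
        non[3] + non[4],       # b: advanced stage, non-recurrent
        rec[1] + rec[2],       # c: early stage, recurrent
        non[1] + non[2],       # d: early stage, non-recurrent
    )
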