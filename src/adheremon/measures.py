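"""Dichotomization of self-reported adherence and viral load.

Self-report is a 30-day recall ("on how many days did you miss at least one
dose?"); it is dichotomized at the same >4 missed-days cut-off used for the
electronic measure.  Viral load is dichotomized at <50 copies/ml
(suppressed) by default, with <1000 copies/ml as the sensitivity-analysis
cut-off.  A percent-adherence rule (good iff observed adherence >= pct%) is
provided for threshold sensitivity analyses at 95/90/85%.
"""

from __future__ import annotations

import numpy as np

from .events import CATEGORY_GOOD, CATEGORY_POOR

#: viral-load cut-offs, copies/ml
VL_CUTOFF_PRIMARY = 50.0
VL_CUTOFF_SENSITIVITY = 1000.0


def _as_array(x):
    arr = np.asarray(x)
    return arr, arr.ndim == 0


def dichotomize_sr(days_missed_recall, threshold: int = 4):
    """Categorize a 30-day missed-days recall as good/poor adherence.

    good iff ``days_missed_recall <= threshold`` (default 4: "more than 4
    days a month" is poor).  Accepts scalars or array-likes; recalls outside
    0..30 raise.
    """
    arr, scalar = _as_array(days_missed_recall)
    if np.any((arr < 0) | (arr > 30)):
        raise ValueError("days_missed_recall must be within 0..30")
    out = np.where(arr > threshold, CATEGORY_POOR, CATEGORY_GOOD)
    return out.item() if scalar else out


def classify_viral_load(copies_per_ml, cutoff: float = VL_CUTOFF_PRIMARY):
    """True iff suppressed: strictly fewer than ``cutoff`` copies/ml.

    A value exactly at the cut-off is unsuppressed (strict inequality, as
    the suppressed/unsuppressed definitions print it).
    """
    arr, scalar = _as_array(copies_per_ml)
    if np.any(arr < 0):
        raise ValueError("copies_per_ml must be non-negative")
    out = arr < cutoff
    return bool(out) if scalar else out


def percent_adherence_threshold(days_missed, days_observed, pct: float):
    """Good iff observed percent adherence is at least ``pct``.

    Percent adherence is ``(days_observed - days_missed) / days_observed``
    on the observed days of a window.  Used for the 95/90/85% threshold
    sensitivity analyses; at pct just above 86.6 on a full 30-day window it
    coincides with the >4 missed-days rule.
    """
    if not (0 < pct <= 100):
        raise ValueError("pct must lie in (0, 100]")
    dm, scalar_m = _as_array(days_missed)
    do, scalar_o = _as_array(days_observed)
    if np.any((do <= 0) | (do > 30)):
        raise ValueError("days_observed must lie in 1..30")
    if np.any(dm > do):
        raise ValueError("days_missed cannot exceed days_observed")
    adherence = (do - dm) / do * 100.0
    out = np.where(adherence >= pct, CATEGORY_GOOD, CATEGORY_POOR)
    return out.item() if (scalar_m and scalar_o) else out
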