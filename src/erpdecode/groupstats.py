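"""Window-aggregated decoding accuracy and the Age × Creativity × Time ANOVA.

Per-subject decoding accuracy is averaged within five 100-ms windows
(100-200, 200-300, 300-400, 400-500, 500-600 ms; half-open on the decoded
grid so shared boundaries are not double-counted) and the aggregates enter a
mixed ANOVA with age and creativity as between-subject factors and time
window as the within-subject factor. The smoothed accuracy series is
aggregated by default — the same series the cluster statistics test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .anova import mixed_anova, tukey_posthoc
from .decoding import AccuracyTimeSeries

DEFAULT_WINDOWS = (
    (100.0, 200.0),
    (200.0, 300.0),
    (300.0, 400.0),
    (400.0, 500.0),
    (500.0, 600.0),
)


def aggregate_windows(
    acc_list: list[AccuracyTimeSeries],
    windows=DEFAULT_WINDOWS,
    use_smoothed: bool = True,
) -> pd.DataFrame:
    """One row per subject × window with the mean accuracy inside [lo, hi)."""
    rows = []
    for acc in acc_list:
        series = acc.accuracy if use_smoothed else acc.accuracy_raw
        for lo, hi in windows:
            mask = (acc.times >= lo) & (acc.times < hi)
            if not mask.any():
                raise ValueError(f"window [{lo}, {hi}) outside the decoded grid")
            rows.append({
                "subject": acc.subject,
                "age_group": acc.group.get("age"),
                "creativity_group": acc.group.get("creativity"),
                "window": f"{int(lo)}-{int(hi)}",
                "mean_accuracy": float(series[mask].mean()),
                "n_points": int(mask.sum()),
            })
    return pd.DataFrame(rows)


def decoding_anova(rows: pd.DataFrame,
                   between=("age_group", "creativity_group"),
                   within=("window",),
                   dv: str = "mean_accuracy") -> pd.DataFrame:
    """Mixed ANOVA on the window aggregates (balanced designs only)."""
    return mixed_anova(rows, dv=dv, subject="subject",
                       between=list(between), within=list(within))


def decoding_tukey(rows: pd.DataFrame, factors,
                   between=("age_group", "creativity_group"),
                   within=("window",),
                   dv: str = "mean_accuracy") -> pd.DataFrame:
    """Tukey HSD post-hoc on window-aggregate cells."""
    return tukey_posthoc(rows, dv=dv, subject="subject",
                         between=list(between), within=list(within),
                         factors=factors)
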