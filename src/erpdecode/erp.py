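"""ERP component measures on ROI-averaged evoked waveforms.

Measures follow the parieto-occipital component conventions: the early
positivity (P1) is the largest positivity within 30-130 ms, quantified as the
mean amplitude within ±5 ms around its peak; the subsequent negativity (N1,
largest negativity within 100-200 ms) is quantified only through peak-to-peak
differences (P1-N1 and N1 to the largest 200-300 ms positivity), because a
superimposed positivity makes its absolute amplitude group-dependent; and the
late positivity is summarized by mean amplitudes in four 100-ms windows from
200 to 600 ms. Windows are half-open; argmax ties resolve to the earliest
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import ROIS, find_channels
from .epochs import EpochSet
from .sequence import STANDARD_AMBIGUOUS, STANDARD_UNAMBIGUOUS

STIMULUS_NAMES = {
    STANDARD_UNAMBIGUOUS: "unambiguous",
    STANDARD_AMBIGUOUS: "ambiguous",
}


@dataclass(frozen=True)
class PeakResult:
    latency: float       # ms
    amplitude: float     # μV
    degenerate: bool     # flat search window


def evoked_average(epochs: EpochSet, condition: str) -> np.ndarray:
    """Sample-wise mean (channels × samples) across one condition's epochs."""
    sel = epochs.conditions == condition
    if not sel.any():
        raise ValueError(f"no epochs with condition {condition!r}")
    return epochs.data[sel].mean(axis=0)


def roi_timeseries(evoked: np.ndarray, channel_names, roi_channels) -> np.ndarray:
    """Unweighted mean across the ROI's channels."""
    idx = find_channels(roi_channels, channel_names)
    return evoked[idx, :].mean(axis=0)


def peak_measure(times, ts, window=(30.0, 130.0), polarity: int = +1,
                 integrate_ms: float | None = 5.0) -> PeakResult:
    """Polarity-signed extremum within the half-open window.

    Amplitude is the mean over [latency - integrate_ms, latency + integrate_ms]
    (clipped to the epoch) when ``integrate_ms`` is given, else the point
    value. Flat windows return the first sample with a degenerate flag.
    """
    times = np.asarray(times)
    ts = np.asarray(ts)
    mask = (times >= window[0]) & (times < window[1])
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    seg = ts[mask]
    seg_t = times[mask]
    degenerate = bool(np.ptp(seg) == 0)
    k = int(np.argmax(polarity * seg))  # ties -> earliest sample
    latency = float(seg_t[k])
    if integrate_ms is None:
        amplitude = float(seg[k])
    else:
        imask = (times >= latency - integrate_ms) & (times <= latency + integrate_ms)
        amplitude = float(ts[imask].mean())
    return PeakResult(latency=latency, amplitude=amplitude, degenerate=degenerate)


def peak_to_peak(times, ts, pos_window, neg_window,
                 integrate_ms: float | None = None) -> float:
    """Positive-extremum amplitude minus negative-extremum amplitude (μV).

    A genuine opposite-polarity deflection pair therefore yields a positive
    value. Point extrema by default.
    """
    pos = peak_measure(times, ts, pos_window, polarity=+1, integrate_ms=integrate_ms)
    neg = peak_measure(times, ts, neg_window, polarity=-1, integrate_ms=integrate_ms)
    return pos.amplitude - neg.amplitude


def window_mean(times, ts, window) -> float:
    """Arithmetic mean over samples in the half-open window (μV)."""
    times = np.asarray(times)
    mask = (times >= window[0]) & (times < window[1])
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return float(np.asarray(ts)[mask].mean())


P1_WINDOW = (30.0, 130.0)
N1_WINDOW = (100.0, 200.0)
LATE_POSITIVITY_WINDOW = (200.0, 300.0)
MEAN_WINDOWS = ((200.0, 300.0), (300.0, 400.0), (400.0, 500.0), (500.0, 600.0))


def measure_roi_series(times, ts) -> list[dict]:
    """The seven standard measures on one ROI waveform.

    Returns rows with keys measure, latency (peaks only) and amplitude.
    """
    rows = []
    p1 = peak_measure(times, ts, P1_WINDOW, polarity=+1, integrate_ms=5.0)
    rows.append({"measure": "P1", "latency": p1.latency, "amplitude": p1.amplitude})
    rows.append({
        "measure": "P1-N1",
        "latency": np.nan,
        "amplitude": peak_to_peak(times, ts, P1_WINDOW, N1_WINDOW),
    })
    rows.append({
        "measure": "N1-late_positivity",
        "latency": np.nan,
        "amplitude": peak_to_peak(times, ts, LATE_POSITIVITY_WINDOW, N1_WINDOW),
    })
    for lo, hi in MEAN_WINDOWS:
        rows.append({
            "measure": f"mean_{int(lo)}_{int(hi)}",
            "latency": np.nan,
            "amplitude": window_mean(times, ts, (lo, hi)),
        })
    return rows


def build_measure_table(epochsets, rois: dict | None = None) -> pd.DataFrame:
    """Long-format measure table across subjects, stimuli and ROIs.

    One row per subject × stimulus × ROI × measure; raises if any subject is
    missing a stimulus condition.
    """
    rois = rois or ROIS
    rows = []
    for ep in epochsets:
        for cond, stim in STIMULUS_NAMES.items():
            evoked = evoked_average(ep, cond)
            for roi_name, roi_channels in rois.items():
                ts = roi_timeseries(evoked, ep.channel_names, roi_channels)
                for rec in measure_roi_series(ep.times, ts):
                    rows.append({
                        "subject": ep.subject,
                        "age_group": ep.group.get("age"),
                        "creativity_group": ep.group.get("creativity"),
                        "stimulus": stim,
                        "roi": roi_name,
                        **rec,
                    })
    return pd.DataFrame(rows)
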