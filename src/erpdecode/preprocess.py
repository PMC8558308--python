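"""Epoching, baseline correction and peak-to-peak artifact rejection.

Epochs are cut on the half-open grid [start, stop) relative to stimulus
onset: sample k sits at start + k * 1000 / sfreq ms, so a [-100, 1000) ms
window at 1000 Hz has exactly 1100 samples and, after keeping every fourth
point, 275 decoded time points.

Artifact rejection follows a two-sided peak-to-peak rule: an epoch is
rejected when any scalp channel's voltage range exceeds ``max_range`` (a
gross artifact) or — in the default interpretation — when *every* scalp
channel's range falls below ``min_range`` (a flat/disconnected recording).
A stricter per-channel reading of the minimum criterion is selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import EOG_CHANNELS, find_channels
from .epochs import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class Recording:
    """Continuous multichannel recording in μV."""

    data: np.ndarray          # (n_channels, n_samples)
    sfreq: float
    channel_names: list[str]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_brainvision(vhdr_path) -> Recording:
    """Optional reader for BrainVision (.vhdr/.vmrk/.eeg) recordings.

    Requires :mod:`mne`. Data are converted from volts to μV.
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,
        sfreq=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def epoch_data(
    recording: Recording,
    onsets_ms,
    conditions=None,
    window: tuple = (-100.0, 1000.0),
    subject: str = "unknown",
    group: dict | None = None,
) -> EpochSet:
    """Cut epochs around stimulus onsets.

    Events whose window would overlap a recording edge are skipped with a log
    entry. ``conditions`` gives one label per onset (default "event").
    """
    onsets_ms = np.asarray(onsets_ms, dtype=float)
    if conditions is None:
        conditions = ["event"] * len(onsets_ms)
    fs = recording.sfreq
    n_samp = int(round((window[1] - window[0]) * fs / 1000.0))
    offset = int(round(window[0] * fs / 1000.0))
    times = window[0] + np.arange(n_samp) * 1000.0 / fs
    keep_data, keep_cond = [], []
    for onset, cond in zip(onsets_ms, conditions):
        start = int(round(onset * fs / 1000.0)) + offset
        stop = start + n_samp
        if start < 0 or stop > recording.n_samples:
            logger.warning("skipping event at %.1f ms: window outside recording", onset)
            continue
        keep_data.append(recording.data[:, start:stop])
        keep_cond.append(cond)
    data = (
        np.stack(keep_data)
        if keep_data
        else np.empty((0, len(recording.channel_names), n_samp))
    )
    return EpochSet(
        data=data,
        times=times,
        sfreq=fs,
        channel_names=list(recording.channel_names),
        conditions=np.asarray(keep_cond, dtype=object),
        subject=subject,
        group=group or {},
    )


def baseline_correct(epochs: EpochSet, baseline: tuple = (-100.0, 0.0)) -> EpochSet:
    """Subtract each epoch's per-channel mean over [baseline) from all samples."""
    mask = epochs.time_mask(*baseline)
    if not mask.any():
        raise ValueError(f"baseline window {baseline} not covered by epoch")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


@dataclass(frozen=True)
class RejectionRule:
    """Peak-to-peak artifact criteria in μV.

    ``min_mode`` — "all": reject only when every analyzed channel is below
    ``min_range`` (flat-recording detector, the default); "any": reject when
    any single channel is below it.
    """

    max_range: float = 100.0
    min_range: float = 2.0
    min_mode: str = "all"
    exclude_channels: tuple = EOG_CHANNELS

    def __post_init__(self) -> None:
        if self.min_range >= self.max_range:
            raise ValueError("min_range must be below max_range")
        if self.min_mode not in ("all", "any"):
            raise ValueError("min_mode must be 'all' or 'any'")


def reject_artifacts(epochs: EpochSet, rule: RejectionRule = RejectionRule()):
    """Drop artifact epochs; returns (clean EpochSet, rejection log).

    The log is a DataFrame with one row per *rejected* epoch: its index,
    reason ("range_above_max" / "range_below_min") and the extreme range.
    """
    analyzed = [ch for ch in epochs.channel_names
                if ch.upper() not in {c.upper() for c in rule.exclude_channels}]
    idx = find_channels(analyzed, epochs.channel_names)
    ranges = np.ptp(epochs.data[:, idx, :], axis=2)  # epochs × channels
    too_big = (ranges > rule.max_range).any(axis=1)
    if rule.min_mode == "all":
        too_small = (ranges < rule.min_range).all(axis=1)
    else:
        too_small = (ranges < rule.min_range).any(axis=1)
    rejected = too_big | too_small
    rows = []
    for e in np.flatnonzero(rejected):
        if too_big[e]:
            rows.append({"epoch": int(e), "reason": "range_above_max",
                         "extreme_range_uv": float(ranges[e].max())})
        else:
            rows.append({"epoch": int(e), "reason": "range_below_min",
                         "extreme_range_uv": float(ranges[e].min())})
    log = pd.DataFrame(rows, columns=["epoch", "reason", "extreme_range_uv"])
    return epochs.select_epochs(~rejected), log
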