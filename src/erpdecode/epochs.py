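"""Epoched EEG container and its HDF5 on-disk layout.

An :class:`EpochSet` holds an epochs × channels × samples array in microvolts
together with the time axis (ms), sampling rate, channel labels, per-epoch
condition labels and subject/group metadata. Ground-truth effect metadata from
the simulator travels with the object so recovery tests can compare against
what was injected.

HDF5 layout (version 1): datasets ``/data`` (float, μV), ``/times`` (ms),
``/conditions`` (UTF-8 strings); root attributes ``layout_version``,
``sfreq``, ``channel_names``, ``subject``, ``group`` (JSON) and
``ground_truth`` (JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

LAYOUT_VERSION = "1"


@dataclass
class EpochSet:
    data: np.ndarray                 # (n_epochs, n_channels, n_samples), μV
    times: np.ndarray                # ms, one entry per sample
    sfreq: float                     # Hz
    channel_names: list[str]
    conditions: np.ndarray           # str label per epoch
    subject: str = "sim"
    group: dict = field(default_factory=dict)      # e.g. {"age": ..., "creativity": ...}
    ground_truth: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs × channels × samples")
        n_ep, n_ch, n_s = self.data.shape
        if len(self.times) != n_s:
            raise ValueError("time axis length does not match sample count")
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length does not match channel count")
        if len(self.conditions) != n_ep:
            raise ValueError("conditions length does not match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            conditions=self.conditions.copy(),
            channel_names=list(self.channel_names),
            group=dict(self.group),
            ground_truth=list(self.ground_truth),
        )

    def select_epochs(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(self, data=self.data[mask], conditions=self.conditions[mask])

    def select_conditions(self, labels) -> "EpochSet":
        labels = {labels} if isinstance(labels, str) else set(labels)
        return self.select_epochs(np.isin(self.conditions, list(labels)))

    def pick_channels(self, names) -> "EpochSet":
        from .channels import find_channels

        idx = find_channels(names, self.channel_names)
        return replace(
            self,
            data=self.data[:, idx, :],
            channel_names=[self.channel_names[i] for i in idx],
        )

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean sample mask on the half-open interval [start, stop)."""
        return (self.times >= start_ms) & (self.times < stop_ms)

    # ------------------------------------------------------------------ io

    def save_h5(self, path, dtype=None) -> None:
        """Write to HDF5; ``dtype`` (e.g. np.float32) can halve file size."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, dtype=dtype)
            f.create_dataset("times", data=self.times)
            f.create_dataset(
                "conditions",
                data=np.asarray(self.conditions, dtype=object),
                dtype=h5py.string_dtype("utf-8"),
            )
            f.attrs["layout_version"] = LAYOUT_VERSION
            f.attrs["sfreq"] = self.sfreq
            f.attrs["channel_names"] = [str(c) for c in self.channel_names]
            f.attrs["subject"] = str(self.subject)
            f.attrs["group"] = json.dumps(self.group)
            f.attrs["ground_truth"] = json.dumps(self.ground_truth)

    @classmethod
    def load_h5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            if f.attrs.get("layout_version") != LAYOUT_VERSION:
                raise ValueError(f"unsupported EpochSet layout in {path}")
            return cls(
                data=f["data"][()],
                times=f["times"][()],
                sfreq=float(f.attrs["sfreq"]),
                channel_names=[str(c) for c in f.attrs["channel_names"]],
                conditions=np.array([c.decode() if isinstance(c, bytes) else str(c)
                                     for c in f["conditions"][()]], dtype=object),
                subject=str(f.attrs["subject"]),
                group=json.loads(f.attrs["group"]),
                ground_truth=json.loads(f.attrs["ground_truth"]),
            )
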