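"""Electrode montage constants for a 32-channel extended 10-20 recording.

The montage covers the 27 scalp sites used for multivariate decoding, the
three parieto-occipital regions of interest used for ERP component
measurement, plus bipolar HEOG/VEOG channels that are recorded but excluded
from every scalp analysis.
"""

from __future__ import annotations

# 32 scalp locations (extended 10-20). The set is chosen to contain every
# electrode named by the decoding montage and the parieto-occipital ROIs.
SCALP_32: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FCz", "FC4",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

EOG_CHANNELS: tuple[str, ...] = ("HEOG", "VEOG")

ALL_CHANNELS: tuple[str, ...] = SCALP_32 + EOG_CHANNELS

# 27 electrodes entering the per-timepoint decoding feature vectors.
DECODING_27: tuple[str, ...] = (
    "F7", "F3", "FC3", "C3", "Fz", "Cz", "F8", "F4", "FC4", "C4",
    "CP5", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "T7", "T8",
)

# Parieto-occipital regions of interest for ERP component measurement.
ROIS: dict[str, tuple[str, ...]] = {
    "left": ("P7", "P3", "PO7", "PO3", "O1"),
    "middle": ("Pz", "POz", "Oz"),
    "right": ("P8", "P4", "PO8", "PO4", "O2"),
}

PARIETO_OCCIPITAL: tuple[str, ...] = ROIS["left"] + ROIS["middle"] + ROIS["right"]


def _canon(name: str) -> str:
    return name.strip().upper()


def find_channels(names, available) -> list[int]:
    """Map channel ``names`` to indices into ``available`` (case-insensitive).

    Raises ``KeyError`` naming the first missing channel.
    """
    lookup = {_canon(ch): i for i, ch in enumerate(available)}
    idx = []
    for name in names:
        key = _canon(name)
        if key not in lookup:
            raise KeyError(f"channel {name!r} not present in recording")
        idx.append(lookup[key])
    return idx
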