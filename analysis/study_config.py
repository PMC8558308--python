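"""Shared study configuration for the analysis drivers.

The synthetic study mirrors the oddball design: four groups (age ×
creativity), six 80-trial blocks per subject (216 standards of each type),
1000 Hz sampling, and evoked responses carrying an early positivity, a
negativity and a late positivity over parieto-occipital scalp. The ground
truth planted for the narrative is an ambiguity effect — ambiguous standards
evoke a +2 μV larger late positivity (300-500 ms, parieto-occipital
channels) — present only in the two creative groups, so decoding should
separate the groups while the less-creative groups stay at chance.

The drivers default to 3 subjects per group so the whole pipeline runs in a
few minutes on one core; pass --n-per-group 12 for the full-scale design.
"""

from __future__ import annotations

from pathlib import Path

import erpdecode as ed
from erpdecode.channels import DECODING_27, PARIETO_OCCIPITAL

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

AMBIGUITY_EFFECT_UV = 2.0
EFFECT_WINDOW_MS = (300.0, 500.0)
NOISE_SD_UV = 10.0


def study_config(n_per_group: int = 3, seed: int = 0) -> ed.SimConfig:
    effects = (
        ed.EffectSpec(
            window=EFFECT_WINDOW_MS,
            channels=PARIETO_OCCIPITAL,
            delta_amplitude=AMBIGUITY_EFFECT_UV,
            condition="standard_ambiguous",
            creativity="creative",
        ),
    )
    return ed.SimConfig(
        channel_names=tuple(DECODING_27),
        noise_sd=NOISE_SD_UV,
        effects=effects,
        groups=tuple(
            ed.GroupSpec(a, c, n_per_group)
            for a in ("younger", "older")
            for c in ("less_creative", "creative")
        ),
        seed=seed,
    )


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
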