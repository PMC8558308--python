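"""Synthetic visual-oddball EEG with known ground truth.

Evoked responses are built as sums of Gaussian-time-course components (an
early lateral parieto-occipital positivity ~100 ms, a subsequent negativity,
and a long-lasting late positivity), each with a per-channel topography.
Condition (stimulus ambiguity) and group (age × creativity) differences are
injected as additive boxcar amplitude shifts over a time window and channel
subset, so every downstream stage can be checked against what was put in.

Noise is independent Gaussian per channel, temporally low-pass filtered at
30 Hz and rescaled so the requested per-sample standard deviation refers to
the filtered series; an optional spatial mixing stage adds realistic
inter-electrode correlation. Identical (config, seed) yields bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .channels import ALL_CHANNELS, PARIETO_OCCIPITAL, ROIS, find_channels
from .epochs import EpochSet
from .sequence import (
    DEVIANT,
    STANDARD_AMBIGUOUS,
    STANDARD_UNAMBIGUOUS,
    SequenceSpec,
    TrialSequence,
    generate_sequence,
)

AGE_GROUPS = ("younger", "older")
CREATIVITY_GROUPS = ("less_creative", "creative")


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component: Gaussian time course times a fixed topography.

    ``temporal_width`` is the Gaussian standard deviation in ms. ``topography``
    maps channel name → unitless weight with max |weight| = 1; channels not
    listed get weight 0.
    """

    name: str
    peak_latency: float            # ms
    temporal_width: float          # ms (Gaussian SD)
    polarity: int                  # +1 or -1
    base_amplitude: float          # μV at the peak for weight-1 channels
    topography: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temporal_width <= 0:
            raise ValueError("temporal_width must be positive")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.topography:
            m = max(abs(v) for v in self.topography.values())
            if m > 1 + 1e-9:
                raise ValueError("topography weights must satisfy max |w| = 1")

    def waveform(self, times: np.ndarray, channel_names) -> np.ndarray:
        """Deterministic (channels × samples) contribution in μV."""
        try:
            idx = find_channels(self.topography.keys(), channel_names)
        except KeyError as err:
            raise KeyError(f"component {self.name!r}: {err}") from err
        topo = np.zeros(len(channel_names))
        for i, w in zip(idx, self.topography.values()):
            topo[i] = w
        g = np.exp(-0.5 * ((times - self.peak_latency) / self.temporal_width) ** 2)
        return self.polarity * self.base_amplitude * np.outer(topo, g)


@dataclass(frozen=True)
class EffectSpec:
    """Additive boxcar amplitude shift on [window) for matching epochs.

    ``condition``/``age``/``creativity`` restrict which epochs receive the
    shift; any selector left as None matches everything.
    """

    window: tuple          # (start_ms, stop_ms), half-open
    channels: tuple        # channel subset receiving the shift
    delta_amplitude: float  # μV
    condition: str | None = None       # e.g. "standard_ambiguous"
    age: str | None = None             # e.g. "older"
    creativity: str | None = None      # e.g. "creative"

    def matches(self, condition: str, group: dict) -> bool:
        if self.condition is not None and condition != self.condition:
            return False
        if self.age is not None and group.get("age") != self.age:
            return False
        if self.creativity is not None and group.get("creativity") != self.creativity:
            return False
        return True

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "channels": list(self.channels),
            "delta_amplitude": self.delta_amplitude,
            "condition": self.condition,
            "age": self.age,
            "creativity": self.creativity,
        }


def default_components(channel_names=None) -> list[ComponentSpec]:
    """P1-like, N1-like and late-positivity components over parieto-occipital
    scalp, with latencies/widths sitting inside the measurement windows used
    downstream (P1 searched 30-130 ms, N1 100-200 ms, late windows 200-600 ms).

    When ``channel_names`` is given, topographies are restricted to channels
    present in it (so reduced montages can reuse the defaults).
    """
    lateral = {ch: 1.0 for ch in ROIS["left"] + ROIS["right"]}
    lateral.update({ch: 0.6 for ch in ROIS["middle"]})
    broad = {ch: 1.0 for ch in PARIETO_OCCIPITAL}
    broad.update({ch: 0.5 for ch in ("CP1", "CP2", "CP5", "CP6")})
    if channel_names is not None:
        have = {c.upper() for c in channel_names}
        lateral = {c: w for c, w in lateral.items() if c.upper() in have}
        broad = {c: w for c, w in broad.items() if c.upper() in have}
    return [
        ComponentSpec("P1", peak_latency=100.0, temporal_width=18.0,
                      polarity=+1, base_amplitude=5.0, topography=lateral),
        ComponentSpec("N1", peak_latency=160.0, temporal_width=24.0,
                      polarity=-1, base_amplitude=7.0, topography=broad),
        ComponentSpec("late_positivity", peak_latency=400.0, temporal_width=130.0,
                      polarity=+1, base_amplitude=4.0, topography=broad),
    ]


@dataclass(frozen=True)
class GroupSpec:
    age: str
    creativity: str
    n_subjects: int = 12

    @property
    def label(self) -> str:
        return f"{self.age}_{self.creativity}"


def default_groups(n_subjects: int = 12) -> list[GroupSpec]:
    return [GroupSpec(a, c, n_subjects) for a in AGE_GROUPS for c in CREATIVITY_GROUPS]


@dataclass(frozen=True)
class SimConfig:
    channel_names: tuple = ALL_CHANNELS
    sfreq: float = 1000.0
    epoch_window: tuple = (-100.0, 1000.0)   # ms, half-open
    components: tuple = None                 # defaults to default_components()
    effects: tuple = ()
    noise_sd: float = 10.0                   # μV per sample after filtering
    noise_model: str = "lowpass_gaussian"    # or "white", "lowpass_gaussian_spatial"
    noise_lowpass_hz: float = 30.0
    spatial_mixing_lambda: float = 0.04      # m, Gaussian kernel scale
    groups: tuple = None                     # defaults to default_groups()
    sequence_spec: SequenceSpec = SequenceSpec()
    per_subject_sequences: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if self.components is None:
            object.__setattr__(
                self, "components", tuple(default_components(self.channel_names))
            )
        if self.groups is None:
            object.__setattr__(self, "groups", tuple(default_groups()))
        for g in self.groups:
            if g.n_subjects < 2:
                raise ValueError("each group needs n_subjects >= 2 for statistics")

    @property
    def times(self) -> np.ndarray:
        """Half-open epoch grid: sample k at window[0] + k * 1000 / sfreq ms."""
        n = int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sfreq / 1000.0))
        return self.epoch_window[0] + np.arange(n) * 1000.0 / self.sfreq


def evoked_truth(config: SimConfig, condition: str, group: dict | None = None) -> np.ndarray:
    """Deterministic class-mean waveform (channels × samples) in μV."""
    group = group or {}
    times = config.times
    wave = np.zeros((len(config.channel_names), len(times)))
    for comp in config.components:
        wave += comp.waveform(times, config.channel_names)
    for eff in config.effects:
        if eff.matches(condition, group):
            idx = find_channels(eff.channels, config.channel_names)
            tmask = (times >= eff.window[0]) & (times < eff.window[1])
            wave[np.ix_(idx, np.flatnonzero(tmask))] += eff.delta_amplitude
    return wave


def _spatial_mixing_matrix(channel_names, lam: float) -> np.ndarray:
    """Distance-based Gaussian mixing kernel over scalp electrodes.

    Uses standard 10-20 positions (via mne's bundled montage); EOG channels
    are left unmixed. Rows are normalized so per-channel noise variance is
    preserved.
    """
    import mne

    try:
        montage = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older mne releases name this montage differently
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    lookup = {k.upper(): v for k, v in pos.items()}
    n = len(channel_names)
    M = np.eye(n)
    coords = {}
    for i, ch in enumerate(channel_names):
        if ch.upper() in lookup:
            coords[i] = lookup[ch.upper()]
    for i, xi in coords.items():
        row = np.zeros(n)
        for j, xj in coords.items():
            d2 = float(np.sum((xi - xj) ** 2))
            row[j] = np.exp(-d2 / (2.0 * lam**2))
        M[i] = row / np.sqrt(np.sum(row**2))
    return M


def _make_noise(config: SimConfig, shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Noise array (epochs, channels, samples) with per-sample SD noise_sd."""
    if config.noise_sd == 0:
        return np.zeros(shape)
    if config.noise_model == "white":
        return config.noise_sd * rng.standard_normal(shape, dtype=np.float32)
    if config.noise_model not in ("lowpass_gaussian", "lowpass_gaussian_spatial"):
        raise ValueError(f"unknown noise model {config.noise_model!r}")
    # pad the time axis so the filter's startup transient is trimmed away;
    # float32 generation halves memory traffic and stays seed-deterministic
    pad = int(round(0.3 * config.sfreq))
    noise = rng.standard_normal(shape[:-1] + (shape[-1] + pad,), dtype=np.float32)
    sos = signal.butter(4, config.noise_lowpass_hz, fs=config.sfreq, output="sos")
    noise = signal.sosfilt(sos, noise, axis=-1)[..., pad:]
    noise *= 1.0 / noise.std()
    if config.noise_model == "lowpass_gaussian_spatial":
        M = _spatial_mixing_matrix(config.channel_names, config.spatial_mixing_lambda)
        noise = np.einsum("ij,ejs->eis", M, noise)
    return config.noise_sd * noise


def simulate_subject_epochs(
    config: SimConfig,
    subject_id: str,
    group: dict,
    seq: TrialSequence | None = None,
    seed: int = 0,
) -> EpochSet:
    """Simulate one subject's epoched session.

    One epoch per trial of ``seq`` (deviants included but labelled, so
    downstream stages can drop them). Class means equal
    :func:`evoked_truth` exactly when ``noise_sd`` is 0.
    """
    rng = np.random.default_rng(seed)
    if seq is None:
        seq = generate_sequence(config.sequence_spec, seed=int(rng.integers(2**31)))
    times = config.times
    conditions = np.asarray(seq.labels, dtype=object)
    truths = {
        cond: evoked_truth(config, cond, group)
        for cond in (DEVIANT, STANDARD_UNAMBIGUOUS, STANDARD_AMBIGUOUS)
    }
    n_ep = len(conditions)
    data = np.empty((n_ep, len(config.channel_names), len(times)))
    for cond, truth in truths.items():
        data[conditions == cond] = truth
    data += _make_noise(config, data.shape, rng)
    return EpochSet(
        data=data,
        times=times,
        sfreq=config.sfreq,
        channel_names=list(config.channel_names),
        conditions=conditions,
        subject=subject_id,
        group=dict(group),
        ground_truth=[e.to_dict() for e in config.effects],
    )


def simulate_study(config: SimConfig, seed: int | None = None):
    """Yield (subject_id, EpochSet) for every subject of every group.

    Per-subject seeds are spawned from the master seed; stimulus sequences
    are re-randomized per subject by default (configurable).
    """
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    fixed_seq = None
    if not config.per_subject_sequences:
        fixed_seq = generate_sequence(config.sequence_spec, seed=master)
    for grp in config.groups:
        for k in range(grp.n_subjects):
            child = ss.spawn(1)[0]
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            subject_id = f"{grp.label}_{k:02d}"
            seq = fixed_seq
            yield simulate_subject_epochs(
                config,
                subject_id,
                {"age": grp.age, "creativity": grp.creativity},
                seq=seq,
                seed=sub_seed,
            )


# ------------------------------------------------------------- creativity

SUBTESTS = ("circles", "incomplete_figures")
SCORE_VARS = ("F", "O", "E", "C", "CS")


def default_creativity_means() -> pd.DataFrame:
    """Plausible figural-test raw-score means per age group and subtest.

    Resistance to premature closure (C) is only scored for the incomplete
    figures subtest; creative strengths (CS) is a whole-test score repeated
    on each row.
    """
    rows = []
    base = {
        ("younger", "circles"): dict(F=22.0, O=16.0, E=28.0, C=np.nan, CS=11.0),
        ("younger", "incomplete_figures"): dict(F=9.0, O=12.0, E=24.0, C=14.0, CS=11.0),
        ("older", "circles"): dict(F=18.0, O=12.0, E=24.0, C=np.nan, CS=9.0),
        ("older", "incomplete_figures"): dict(F=8.0, O=10.0, E=21.0, C=12.0, CS=9.0),
    }
    for (age, subtest), vals in base.items():
        rows.append(dict(age_group=age, subtest=subtest, **vals))
    return pd.DataFrame(rows)


def simulate_creativity_scores(
    group_means: pd.DataFrame | None = None,
    spread: pd.DataFrame | float = 0.25,
    n_per_group: int = 36,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-participant raw figural-test scores.

    ``group_means`` is a table with columns age_group, subtest, F, O, E, C, CS;
    ``spread`` is either a like-shaped table of standard deviations or a
    single coefficient of variation applied to every mean. Fluency draws are
    resampled until strictly positive (ratios divide by F).
    """
    rng = np.random.default_rng(seed)
    means = default_creativity_means() if group_means is None else group_means
    if (means["F"] <= 0).any():
        raise ValueError("fluency means must be strictly positive")
    rows = []
    for age in means["age_group"].unique():
        sub_means = means[means["age_group"] == age].set_index("subtest")
        for p in range(n_per_group):
            pid = f"{age}_{p:03d}"
            cs_val = None
            for subtest in sub_means.index:
                rec = {"participant": pid, "age_group": age, "subtest": subtest}
                for var in SCORE_VARS:
                    mu = sub_means.loc[subtest, var]
                    if np.isnan(mu):
                        rec[var] = np.nan
                        continue
                    if isinstance(spread, pd.DataFrame):
                        sd = spread.set_index(["age_group", "subtest"]).loc[(age, subtest), var]
                    else:
                        sd = spread * mu
                    val = rng.normal(mu, sd)
                    if var == "F":
                        while val <= 0:
                            val = rng.normal(mu, sd)
                    else:
                        val = max(val, 0.0)
                    if var == "CS":
                        # whole-test score: one draw per participant
                        if cs_val is None:
                            cs_val = val
                        val = cs_val
                    rec[var] = val
                rows.append(rec)
    return pd.DataFrame(rows)
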