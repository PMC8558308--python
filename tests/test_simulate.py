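"""Synthetic EEG generator: ground-truth identities, linearity, determinism."""

import numpy as np
import pytest

import erpdecode as ed
from erpdecode.channels import DECODING_27, PARIETO_OCCIPITAL
from erpdecode.sequence import STANDARD_AMBIGUOUS, STANDARD_UNAMBIGUOUS
from erpdecode.simulate import default_creativity_means, evoked_truth

GROUP = {"age": "younger", "creativity": "creative"}


def _class_mean(ep, cond):
    return ep.data[ep.conditions == cond].mean(axis=0)


def test_noiseless_class_mean_equals_component_sum(noiseless_epochs):
    ep, cfg = noiseless_epochs
    for cond in (STANDARD_UNAMBIGUOUS, STANDARD_AMBIGUOUS):
        expected = evoked_truth(cfg, cond, GROUP)
        # averaging identical epochs is exact up to float accumulation
        np.testing.assert_allclose(_class_mean(ep, cond), expected, atol=1e-12)


def test_no_effect_means_identical_class_truth(noiseless_epochs):
    ep, cfg = noiseless_epochs
    assert cfg.effects == ()
    np.testing.assert_array_equal(
        _class_mean(ep, STANDARD_UNAMBIGUOUS), _class_mean(ep, STANDARD_AMBIGUOUS)
    )


def test_injected_effect_shifts_only_target_window_and_channels():
    eff = ed.EffectSpec(window=(300.0, 500.0), channels=("PO3", "PO4"),
                        delta_amplitude=2.0, condition=STANDARD_AMBIGUOUS)
    cfg = ed.SimConfig(noise_sd=0.0, effects=(eff,))
    amb = evoked_truth(cfg, STANDARD_AMBIGUOUS, GROUP)
    unamb = evoked_truth(cfg, STANDARD_UNAMBIGUOUS, GROUP)
    diff = amb - unamb
    times = cfg.times
    chans = [cfg.channel_names.index("PO3"), cfg.channel_names.index("PO4")]
    win = (times >= 300) & (times < 500)
    np.testing.assert_allclose(diff[np.ix_(chans, np.flatnonzero(win))], 2.0,
                               atol=1e-12)
    diff[np.ix_(chans, np.flatnonzero(win))] = 0.0
    np.testing.assert_allclose(diff, 0.0, atol=1e-12)


def test_group_selector_restricts_effect():
    eff = ed.EffectSpec(window=(300.0, 500.0), channels=("PO3",),
                        delta_amplitude=2.0, condition=STANDARD_AMBIGUOUS,
                        age="older")
    cfg = ed.SimConfig(noise_sd=0.0, effects=(eff,))
    young = evoked_truth(cfg, STANDARD_AMBIGUOUS, {"age": "younger", "creativity": "creative"})
    old = evoked_truth(cfg, STANDARD_AMBIGUOUS, {"age": "older", "creativity": "creative"})
    assert not np.array_equal(young, old)
    np.testing.assert_array_equal(
        young, evoked_truth(cfg, STANDARD_UNAMBIGUOUS, {"age": "younger", "creativity": "creative"})
    )


def test_simulator_linearity_in_amplitude():
    cfg1 = ed.SimConfig(noise_sd=0.0)
    doubled = tuple(
        ed.ComponentSpec(c.name, c.peak_latency, c.temporal_width, c.polarity,
                         2 * c.base_amplitude, c.topography)
        for c in cfg1.components
    )
    cfg2 = ed.SimConfig(noise_sd=0.0, components=doubled)
    w1 = evoked_truth(cfg1, STANDARD_UNAMBIGUOUS, GROUP)
    w2 = evoked_truth(cfg2, STANDARD_UNAMBIGUOUS, GROUP)
    np.testing.assert_allclose(w2, 2 * w1, rtol=0, atol=1e-12)


def test_seed_determinism_bit_identical(small_simconfig):
    seq = ed.generate_sequence(small_simconfig.sequence_spec, seed=4)
    a = ed.simulate_subject_epochs(small_simconfig, "s", GROUP, seq=seq, seed=99)
    b = ed.simulate_subject_epochs(small_simconfig, "s", GROUP, seq=seq, seed=99)
    assert np.array_equal(a.data, b.data)
    c = ed.simulate_subject_epochs(small_simconfig, "s", GROUP, seq=seq, seed=100)
    assert not np.array_equal(a.data, c.data)


def test_effect_recovery_from_noisy_epochs():
    """A +2 μV ambiguity effect at parieto-occipital channels is recovered in
    the 300-500 ms window-mean condition difference to within ±0.5 μV."""
    eff = ed.EffectSpec(window=(300.0, 500.0), channels=PARIETO_OCCIPITAL,
                        delta_amplitude=2.0, condition=STANDARD_AMBIGUOUS)
    cfg = ed.SimConfig(noise_sd=10.0, effects=(eff,))
    seq = ed.generate_sequence(cfg.sequence_spec, seed=31)  # 216 trials/class
    ep = ed.simulate_subject_epochs(cfg, "s", GROUP, seq=seq, seed=32)
    tmask = ep.time_mask(300.0, 500.0)
    chans = [ep.channel_names.index(c) for c in PARIETO_OCCIPITAL]
    amb = _class_mean(ep, STANDARD_AMBIGUOUS)
    unamb = _class_mean(ep, STANDARD_UNAMBIGUOUS)
    diff = (amb - unamb)[np.ix_(chans, np.flatnonzero(tmask))].mean()
    assert abs(diff - 2.0) < 0.5


def test_topography_channel_mismatch_is_an_error():
    comp = ed.ComponentSpec("bad", 100.0, 20.0, +1, 5.0, {"XX9": 1.0})
    cfg = ed.SimConfig(noise_sd=0.0, components=(comp,))
    with pytest.raises(KeyError, match="XX9"):
        evoked_truth(cfg, STANDARD_UNAMBIGUOUS, GROUP)


def test_noise_models_differ_and_spatial_mixing_correlates():
    base = dict(channel_names=tuple(DECODING_27), noise_sd=5.0,
                sequence_spec=ed.SequenceSpec(n_blocks=1))
    seq = ed.generate_sequence(base["sequence_spec"], seed=1)
    eps = {}
    for model in ("white", "lowpass_gaussian", "lowpass_gaussian_spatial"):
        cfg = ed.SimConfig(noise_model=model, **base)
        eps[model] = ed.simulate_subject_epochs(cfg, "s", GROUP, seq=seq, seed=5)
    resid = {m: e.data - e.data.mean(axis=0, keepdims=True) for m, e in eps.items()}

    def neighbor_corr(x):
        a = x[:, DECODING_27.index("PO3"), :].ravel()
        b = x[:, DECODING_27.index("POz"), :].ravel()
        return np.corrcoef(a, b)[0, 1]

    assert abs(neighbor_corr(resid["white"])) < 0.05
    assert abs(neighbor_corr(resid["lowpass_gaussian"])) < 0.05
    assert neighbor_corr(resid["lowpass_gaussian_spatial"]) > 0.3
    # low-passed noise is temporally smooth, white noise is not
    def lag1(x):
        a = x[:, 0, :-1].ravel(); b = x[:, 0, 1:].ravel()
        return np.corrcoef(a, b)[0, 1]
    assert lag1(resid["white"]) < 0.1
    assert lag1(resid["lowpass_gaussian"]) > 0.9


def test_noise_sd_is_honoured():
    cfg = ed.SimConfig(channel_names=tuple(DECODING_27), noise_sd=7.0,
                       sequence_spec=ed.SequenceSpec(n_blocks=1))
    seq = ed.generate_sequence(cfg.sequence_spec, seed=2)
    ep = ed.simulate_subject_epochs(cfg, "s", GROUP, seq=seq, seed=3)
    resid = ep.data - ed.evoked_truth(cfg, STANDARD_UNAMBIGUOUS, GROUP)
    sd = resid[ep.conditions == STANDARD_UNAMBIGUOUS].std()
    assert abs(sd - 7.0) < 0.2


def test_simulate_study_yields_all_groups():
    cfg = ed.SimConfig(
        channel_names=tuple(DECODING_27),
        noise_sd=5.0,
        sequence_spec=ed.SequenceSpec(n_blocks=1),
        groups=tuple(ed.GroupSpec(a, c, 2) for a in ("younger", "older")
                     for c in ("less_creative", "creative")),
    )
    subjects = list(ed.simulate_study(cfg, seed=8))
    assert len(subjects) == 8
    labels = {(e.group["age"], e.group["creativity"]) for e in subjects}
    assert len(labels) == 4
    assert len({e.subject for e in subjects}) == 8


# ----------------------------------------------------------- creativity sim

def test_zero_spread_reproduces_group_means():
    df = ed.simulate_creativity_scores(spread=0.0, n_per_group=3, seed=0)
    means = default_creativity_means().set_index(["age_group", "subtest"])
    for _, row in df.iterrows():
        for var in ("F", "O", "E", "C", "CS"):
            mu = means.loc[(row["age_group"], row["subtest"]), var]
            if np.isnan(mu):
                assert np.isnan(row[var])
            else:
                assert row[var] == pytest.approx(mu)


def test_row_counts_and_positive_fluency():
    df = ed.simulate_creativity_scores(n_per_group=12, seed=1)
    assert (df.groupby("age_group")["participant"].nunique() == 12).all()
    assert len(df) == 12 * 2 * 2  # participants × age groups × subtests
    assert (df["F"] > 0).all()


def test_sample_means_converge_to_configured_means():
    df = ed.simulate_creativity_scores(n_per_group=10_000, seed=2)
    means = default_creativity_means().set_index(["age_group", "subtest"])
    got = df.groupby(["age_group", "subtest"], observed=True)["F"].mean()
    for key, val in got.items():
        mu = means.loc[key, "F"]
        assert abs(val - mu) / mu < 0.02


def test_nonpositive_fluency_mean_rejected():
    bad = default_creativity_means()
    bad.loc[0, "F"] = 0.0
    with pytest.raises(ValueError, match="fluency"):
        ed.simulate_creativity_scores(group_means=bad, n_per_group=2, seed=0)
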