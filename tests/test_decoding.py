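"""Scalp-pattern decoding: SVM correctness, set averaging, smoothing,
end-to-end structure and invariances."""

import numpy as np
import pytest

import erpdecode as ed
from erpdecode._svm import EcocSvm, one_vs_one_code, svm_decision, svm_train
from erpdecode.decoding import (
    accuracy_from_predictions,
    downsample_epochs,
    make_averaged_sets,
    smooth_accuracy,
)
from erpdecode.sequence import STANDARD_AMBIGUOUS, STANDARD_UNAMBIGUOUS

GROUP = {"age": "younger", "creativity": "creative"}


# ------------------------------------------------------------- downsampling

def test_downsample_1100_samples_to_275_points(rng):
    data = rng.normal(size=(4, 3, 1100))
    times = -100.0 + np.arange(1100)
    ep = ed.EpochSet(data, times, 1000.0, ["a", "b", "c"],
                     np.asarray(["x"] * 4, dtype=object))
    out = downsample_epochs(ep, 4)
    assert out.n_samples == 275
    assert out.sfreq == 250.0
    assert out.times[0] == -100.0 and out.times[1] == -96.0
    # retained values are bit-exact copies at the retained indices
    np.testing.assert_array_equal(out.data, data[:, :, ::4])


def test_downsample_step_one_is_identity(rng):
    data = rng.normal(size=(2, 2, 100))
    ep = ed.EpochSet(data, np.arange(100.0), 1000.0, ["a", "b"],
                     np.asarray(["x"] * 2, dtype=object))
    out = downsample_epochs(ep, 1)
    np.testing.assert_array_equal(out.data, data)


def test_downsample_invalid_step(rng):
    ep = ed.EpochSet(rng.normal(size=(1, 1, 10)), np.arange(10.0), 1000.0,
                     ["a"], np.asarray(["x"], dtype=object))
    with pytest.raises(ValueError):
        downsample_epochs(ep, 0)


# ------------------------------------------------------------ averaged sets

def test_averaged_sets_216_trials_split_72(rng):
    X = [rng.normal(size=(216, 5, 10)) for _ in range(2)]
    means, per = make_averaged_sets(X, 3, rng)
    assert per == 72
    assert means.shape == (3, 2, 5, 10)


def test_averaged_sets_discard_remainder(rng):
    X = [rng.normal(size=(7, 2, 4)), rng.normal(size=(7, 2, 4))]
    means, per = make_averaged_sets(X, 3, rng)
    assert per == 2  # 7 // 3, one trial discarded


def test_averaged_sets_match_bruteforce_means():
    rng = np.random.default_rng(0)
    X = [np.arange(6 * 2 * 3, dtype=float).reshape(6, 2, 3), np.zeros((6, 2, 3))]
    rng_used = np.random.default_rng(99)
    perm = np.random.default_rng(99).permutation(6)
    means, per = make_averaged_sets(X, 3, rng_used)
    for s in range(3):
        expected = X[0][perm[2 * s:2 * s + 2]].mean(axis=0)
        np.testing.assert_allclose(means[s, 0], expected, atol=1e-15)


def test_too_few_trials_is_an_error(rng):
    with pytest.raises(ValueError, match="fewer trials"):
        make_averaged_sets([rng.normal(size=(2, 2, 2))], 3, rng)


# ------------------------------------------------------------------- SVM

def test_smo_agrees_with_sklearn_svc():
    """Predictions (and decision values) of the SMO solver match an
    independent reference SVM across random tiny problems."""
    svm = pytest.importorskip("sklearn.svm")
    rng = np.random.default_rng(7)
    n_checked = 0
    for _ in range(200):
        n = int(rng.integers(4, 10))
        d = int(rng.integers(2, 28))
        X = rng.normal(size=(n, d))
        y = np.ones(n)
        y[: n // 2] = -1
        rng.shuffle(y)
        Xt = rng.normal(size=(6, d))
        w, b = svm_train(X, y, C=1.0)
        dec = svm_decision(w, b, Xt)
        ref = svm.SVC(kernel="linear", C=1.0, tol=1e-7).fit(X, (y > 0).astype(int))
        dec_ref = ref.decision_function(Xt)
        keep = np.abs(dec_ref) > 1e-6
        assert np.array_equal(np.sign(dec[keep]), np.sign(dec_ref[keep]))
        n_checked += keep.sum()
    assert n_checked > 1000


def test_svm_matches_margin_maximization_oracle():
    """2-electrode toy: the SMO hyperplane matches a brute-force search over
    hyperplane angles/offsets maximizing the margin (separable, margin small
    enough that no multiplier is clipped at C)."""
    X = np.array([[0.0, 1.2], [0.4, 1.0], [0.2, -1.0], [-0.3, -1.3]])
    y = np.array([1.0, 1.0, -1.0, -1.0])
    w, b = svm_train(X, y, C=1e6)  # effectively hard margin
    # oracle: grid search over unit normals and offsets
    best = (-np.inf, None)
    for theta in np.linspace(0, np.pi, 3601):
        n = np.array([np.cos(theta), np.sin(theta)])
        proj = X @ n
        lo = proj[y > 0].min()
        hi = proj[y < 0].max()
        margin = (lo - hi) / 2.0
        if margin > best[0]:
            best = (margin, n, -(lo + hi) / 2.0)
    margin, n_star, b_star = best
    w_norm = w / np.linalg.norm(w)
    assert abs(float(w_norm @ n_star)) > 0.9999
    # functional margin of the SVM solution is 1/|w| and must equal the oracle
    assert 1.0 / np.linalg.norm(w) == pytest.approx(margin, rel=1e-3)
    grid = np.array([[0.0, 0.5], [0.0, -0.5], [1.0, 0.2], [-1.0, -0.4]])
    oracle_pred = np.sign(grid @ n_star + b_star)
    assert np.array_equal(np.sign(svm_decision(w, b, grid)), oracle_pred)


def test_separable_classes_decode_perfectly():
    train = np.zeros((3, 4, 2))  # (T, exemplars, electrodes)
    train[:, :2, 0] = 5.0    # class 0
    train[:, 2:, 0] = -5.0   # class 1
    test = np.zeros((3, 2, 2))
    test[:, 0, 0] = 4.0
    test[:, 1, 0] = -4.0
    from erpdecode._svm import decode_timepoints_binary
    pred = decode_timepoints_binary(train, test, 1.0)
    assert np.array_equal(pred, np.tile([0, 1], (3, 1)))


def test_ecoc_binary_equals_plain_svm(rng):
    X = rng.normal(size=(8, 5))
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    clf = EcocSvm(C=1.0).fit(X, y)
    assert clf.decision_values(X).shape == (8, 1)  # single dichotomy
    w, b = svm_train(X, np.where(y == 0, 1.0, -1.0), C=1.0)
    Xt = rng.normal(size=(10, 5))
    plain = np.where(svm_decision(w, b, Xt) >= 0, 0, 1)
    assert np.array_equal(clf.predict(Xt), plain)


def test_ecoc_three_classes_one_vs_one(rng):
    centers = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
    X = np.vstack([c + 0.3 * rng.normal(size=(20, 2)) for c in centers])
    y = np.repeat([0, 1, 2], 20)
    code = one_vs_one_code(3)
    assert code.shape == (3, 3)
    clf = EcocSvm(C=1.0).fit(X, y)
    assert (clf.predict(X) == y).mean() > 0.95


# --------------------------------------------------------------- smoothing

def test_smoothing_constant_series_unchanged():
    x = np.full(50, 0.7)
    np.testing.assert_allclose(smooth_accuracy(x, 5), x, atol=1e-15)


def test_smoothing_impulse_spreads_to_five_points():
    x = np.zeros(21)
    x[10] = 1.0
    y = smooth_accuracy(x, 5)
    np.testing.assert_allclose(y[8:13], 0.2, atol=1e-15)
    assert np.all(y[:8] == 0) and np.all(y[13:] == 0)


def test_smoothing_matches_direct_convolution(rng):
    x = rng.uniform(size=101)
    y = smooth_accuracy(x, 5)
    direct = np.convolve(x, np.ones(5) / 5.0, mode="valid")
    np.testing.assert_allclose(y[2:-2], direct, atol=1e-12)
    # shrinking edge windows
    assert y[0] == pytest.approx(x[:3].mean())
    assert y[-1] == pytest.approx(x[-3:].mean())


def test_even_smoothing_window_rejected():
    with pytest.raises(ValueError):
        smooth_accuracy(np.zeros(10), 4)


# ------------------------------------------------------------- end-to-end

def test_accuracy_series_structure(null_subject_accuracy):
    acc = null_subject_accuracy
    assert len(acc.times) == 275
    assert acc.times[0] == -100.0 and acc.times[-1] == 996.0
    assert acc.attempts_per_point == 2 * 3 * 10
    assert np.all((acc.accuracy >= 0) & (acc.accuracy <= 1))
    raw, smoothed = accuracy_from_predictions(acc.predictions, 5)
    np.testing.assert_allclose(acc.accuracy, smoothed, atol=1e-15)
    np.testing.assert_allclose(acc.accuracy_raw, raw, atol=1e-15)


def test_decoding_seed_determinism(small_simconfig):
    seq = ed.generate_sequence(small_simconfig.sequence_spec, seed=41)
    ep = ed.simulate_subject_epochs(small_simconfig, "s", GROUP, seq=seq, seed=42)
    cfg = ed.DecodingConfig(n_iterations=3)
    a = ed.run_decoding(ep, cfg, seed=5)
    b = ed.run_decoding(ep, cfg, seed=5)
    assert np.array_equal(a.predictions, b.predictions)
    c = ed.run_decoding(ep, cfg, seed=6)
    assert not np.array_equal(a.predictions, c.predictions)


def test_electrode_relabeling_invariance(small_simconfig):
    """Consistently permuting electrode labels (and data rows) leaves the
    decoding accuracy unchanged."""
    seq = ed.generate_sequence(small_simconfig.sequence_spec, seed=51)
    ep = ed.simulate_subject_epochs(small_simconfig, "s", GROUP, seq=seq, seed=52)
    cfg = ed.DecodingConfig(n_iterations=3)
    a = ed.run_decoding(ep, cfg, seed=9)
    perm = np.random.default_rng(0).permutation(ep.n_channels)
    ep2 = ed.EpochSet(
        ep.data[:, perm, :], ep.times, ep.sfreq,
        [ep.channel_names[i] for i in perm], ep.conditions,
        subject=ep.subject, group=ep.group,
    )
    b = ed.run_decoding(ep2, cfg, seed=9)
    np.testing.assert_array_equal(a.predictions, b.predictions)


def test_missing_class_or_electrode_raises(small_simconfig):
    seq = ed.generate_sequence(small_simconfig.sequence_spec, seed=61)
    ep = ed.simulate_subject_epochs(small_simconfig, "s", GROUP, seq=seq, seed=62)
    only_unamb = ep.select_conditions([STANDARD_UNAMBIGUOUS, "deviant"])
    with pytest.raises(ValueError, match="class"):
        ed.run_decoding(only_unamb, ed.DecodingConfig(n_iterations=2), seed=1)
    missing = ep.pick_channels(ep.channel_names[:20])
    with pytest.raises(KeyError):
        ed.run_decoding(missing, ed.DecodingConfig(n_iterations=2), seed=1)


def test_identical_distributions_near_chance(null_subject_accuracy):
    """With no class difference, grand-mean accuracy sits at chance within
    3 binomial-scale standard errors."""
    acc = null_subject_accuracy
    grand = acc.accuracy_raw.mean()
    # attempts and time points are correlated, so the tolerance is generous
    assert abs(grand - 0.5) < 0.05


def test_strong_effect_elevates_accuracy_only_post_stimulus(small_simconfig):
    eff = ed.EffectSpec(window=(300.0, 500.0), channels=ed.ROIS["left"] + ed.ROIS["right"],
                        delta_amplitude=4.0, condition=STANDARD_AMBIGUOUS)
    cfg = ed.SimConfig(
        channel_names=small_simconfig.channel_names,
        noise_sd=10.0,
        sequence_spec=small_simconfig.sequence_spec,
        effects=(eff,),
    )
    seq = ed.generate_sequence(cfg.sequence_spec, seed=71)
    ep = ed.simulate_subject_epochs(cfg, "s", GROUP, seq=seq, seed=72)
    acc = ed.run_decoding(ep, ed.DecodingConfig(n_iterations=10), seed=73)
    effect_mask = (acc.times >= 320) & (acc.times < 480)
    base_mask = acc.times < 0
    assert acc.accuracy[effect_mask].mean() > 0.8
    assert abs(acc.accuracy[base_mask].mean() - 0.5) < 0.1


def test_accuracy_h5_roundtrip(tmp_path, null_subject_accuracy):
    path = tmp_path / "acc.h5"
    null_subject_accuracy.save_h5(path)
    back = ed.AccuracyTimeSeries.load_h5(path)
    np.testing.assert_array_equal(back.predictions, null_subject_accuracy.predictions)
    np.testing.assert_allclose(back.accuracy, null_subject_accuracy.accuracy)
    assert back.subject == null_subject_accuracy.subject
    assert back.chance == 0.5


def test_epochset_h5_roundtrip(tmp_path, rng):
    ep = ed.EpochSet(
        rng.normal(size=(3, 2, 10)), np.arange(10.0), 1000.0, ["a", "b"],
        np.asarray(["x", "y", "x"], dtype=object),
        subject="s1", group={"age": "older", "creativity": "creative"},
        ground_truth=[{"delta_amplitude": 2.0}],
    )
    path = tmp_path / "ep.h5"
    ep.save_h5(path)
    back = ed.EpochSet.load_h5(path)
    np.testing.assert_array_equal(back.data, ep.data)
    assert list(back.conditions) == list(ep.conditions)
    assert back.group == ep.group
    assert back.ground_truth == ep.ground_truth


def test_accuracy_monotone_in_effect_size(two_block_spec):
    """Mean accuracy in the effect window is non-decreasing in the injected
    effect size (Monte-Carlo tolerance on a small simulation)."""
    window_means = []
    for delta in (0.0, 1.0, 2.0, 4.0):
        eff = ed.EffectSpec(window=(300.0, 500.0),
                            channels=ed.ROIS["left"] + ed.ROIS["right"],
                            delta_amplitude=delta,
                            condition=STANDARD_AMBIGUOUS)
        cfg = ed.SimConfig(channel_names=tuple(ed.DECODING_27), noise_sd=10.0,
                           sequence_spec=two_block_spec,
                           effects=(eff,) if delta else ())
        vals = []
        for s in range(2):
            seq = ed.generate_sequence(two_block_spec, seed=81 + s)
            ep = ed.simulate_subject_epochs(cfg, f"s{s}", GROUP,
                                            seq=seq, seed=82 + s)
            acc = ed.run_decoding(ep, ed.DecodingConfig(n_iterations=10),
                                  seed=83 + s)
            mask = (acc.times >= 300) & (acc.times < 500)
            vals.append(acc.accuracy[mask].mean())
        window_means.append(np.mean(vals))
    tol = 0.03  # Monte-Carlo slack for neighbouring effect sizes
    for lo, hi in zip(window_means[:-1], window_means[1:]):
        assert hi >= lo - tol
    assert window_means[-1] > window_means[0] + 0.2  # 4 μV is far above chance
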