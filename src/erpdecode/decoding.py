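"""Per-timepoint decoding of stimulus ambiguity from scalp distributions.

For each subject, epochs are down-sampled to one point per 4 ms (250 Hz,
275 points on a [-100, 1000) ms epoch), and at every decoded time point a
linear SVM (within a generic ECOC scheme, which for two classes is a single
binary classifier) is trained on averaged-trial exemplars: each class's
trials are randomly partitioned into three equal sets, set means form a
3 sets × 2 classes × 27 electrodes matrix, two sets per class train the
classifier and the third tests it. Three-fold cross-validation is iterated
50 times with fresh random partitions, giving 2 × 3 × 50 = 300 decoding
attempts per time point; accuracy is their mean, then smoothed with a
5-point moving window (±8 ms). Per-attempt decoder outputs are stored so the
cluster permutation null can be built at the testing stage without
retraining.

Set partitions are drawn once per iteration and shared across time points;
features are z-scored per electrode using training-set statistics only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from ._svm import decode_timepoints_binary
from .channels import DECODING_27, find_channels
from .epochs import EpochSet
from .sequence import STANDARD_AMBIGUOUS, STANDARD_UNAMBIGUOUS

LAYOUT_VERSION = "1"


@dataclass(frozen=True)
class DecodingConfig:
    electrodes: tuple = DECODING_27
    class_conditions: tuple = (STANDARD_UNAMBIGUOUS, STANDARD_AMBIGUOUS)
    n_sets: int = 3
    n_iterations: int = 50
    downsample_step: int = 4
    smoothing_points: int = 5
    svm_C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 2:
            raise ValueError("need at least two sets (train/test split)")
        if self.smoothing_points % 2 == 0:
            raise ValueError("smoothing window must have an odd point count")

    @property
    def chance(self) -> float:
        return 1.0 / len(self.class_conditions)

    @property
    def attempts_per_point(self) -> int:
        return len(self.class_conditions) * self.n_sets * self.n_iterations


@dataclass
class AccuracyTimeSeries:
    """Decoding accuracy per decoded time point, with stored decoder outputs.

    ``predictions[t, i, f, c]`` is the predicted class index for the test
    exemplar whose true class is ``c``, at time point t, iteration i, fold f.
    ``accuracy`` is the smoothed series; ``accuracy_raw`` the unsmoothed one.
    """

    subject: str
    times: np.ndarray            # ms, decoded grid
    accuracy: np.ndarray         # smoothed, in [0, 1]
    accuracy_raw: np.ndarray
    predictions: np.ndarray      # (T, n_iterations, n_folds, n_classes) uint8
    chance: float = 0.5
    group: dict = field(default_factory=dict)
    smoothing_points: int = 5

    @property
    def attempts_per_point(self) -> int:
        return int(np.prod(self.predictions.shape[1:]))

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("accuracy", data=self.accuracy)
            f.create_dataset("accuracy_raw", data=self.accuracy_raw)
            f.create_dataset("times", data=self.times)
            f.create_dataset("outputs", data=self.predictions)
            f.attrs["layout_version"] = LAYOUT_VERSION
            f.attrs["subject"] = self.subject
            f.attrs["chance"] = self.chance
            f.attrs["smoothing_points"] = self.smoothing_points
            f.attrs["group"] = json.dumps(self.group)

    @classmethod
    def load_h5(cls, path) -> "AccuracyTimeSeries":
        with h5py.File(path, "r") as f:
            return cls(
                subject=str(f.attrs["subject"]),
                times=f["times"][()],
                accuracy=f["accuracy"][()],
                accuracy_raw=f["accuracy_raw"][()],
                predictions=f["outputs"][()],
                chance=float(f.attrs["chance"]),
                group=json.loads(f.attrs["group"]),
                smoothing_points=int(f.attrs["smoothing_points"]),
            )


def downsample_epochs(epochs: EpochSet, step: int = 4) -> EpochSet:
    """Keep samples at indices 0, step, 2·step, … (no anti-alias filtering:
    the 30 Hz low-pass applied during preprocessing already band-limits).
    """
    if step < 1 or int(step) != step:
        raise ValueError("downsampling step must be a positive integer")
    step = int(step)
    return replace(
        epochs,
        data=epochs.data[:, :, ::step],
        times=epochs.times[::step],
        sfreq=epochs.sfreq / step,
    )


def make_averaged_sets(class_epochs, n_sets: int, rng: np.random.Generator):
    """Random equal-size partition of each class's trials; returns set means.

    ``class_epochs`` is a sequence of per-class arrays (trials × E × T).
    Remainder trials beyond ``n_sets * floor(n/n_sets)`` are discarded at
    random (the permutation's tail). Returns (means, trials_per_set) with
    means shaped (n_sets, n_classes, E, T).
    """
    n_classes = len(class_epochs)
    E, T = class_epochs[0].shape[1:]
    per = min(x.shape[0] for x in class_epochs) // n_sets
    if per < 1:
        raise ValueError("fewer trials than sets in at least one class")
    means = np.empty((n_sets, n_classes, E, T))
    for c, X in enumerate(class_epochs):
        perm = rng.permutation(X.shape[0])[: n_sets * per]
        for s in range(n_sets):
            means[s, c] = X[perm[s * per:(s + 1) * per]].mean(axis=0)
    return means, per


def smooth_accuracy(series: np.ndarray, points: int = 5) -> np.ndarray:
    """Centred moving average; the window shrinks at the series edges so the
    output has the input's length without padding artifacts.
    """
    if points % 2 == 0:
        raise ValueError("smoothing window must be odd")
    series = np.asarray(series, dtype=float)
    kernel = np.ones(points)
    num = np.convolve(series, kernel, mode="same")
    den = np.convolve(np.ones_like(series), kernel, mode="same")
    return num / den


def accuracy_from_predictions(predictions: np.ndarray,
                              smoothing_points: int = 5):
    """(raw, smoothed) accuracy series from stored decoder outputs."""
    n_classes = predictions.shape[-1]
    truth = np.arange(n_classes, dtype=predictions.dtype)
    correct = predictions == truth  # broadcast on the last axis
    raw = correct.reshape(predictions.shape[0], -1).mean(axis=1)
    return raw, smooth_accuracy(raw, smoothing_points)


def run_decoding(epochs: EpochSet, config: DecodingConfig = DecodingConfig(),
                 seed: int | None = None) -> AccuracyTimeSeries:
    """Full per-subject decoding; deterministic in (epochs, config, seed)."""
    master = config.seed if seed is None else seed
    ep = epochs.pick_channels(config.electrodes)
    ep = downsample_epochs(ep, config.downsample_step)
    class_epochs = []
    for cond in config.class_conditions:
        sel = ep.conditions == cond
        if not sel.any():
            raise ValueError(f"no epochs for class condition {cond!r}")
        class_epochs.append(np.ascontiguousarray(ep.data[sel], dtype=np.float64))
    if len(class_epochs) != 2:
        raise NotImplementedError(
            "the averaged-set pipeline is implemented for the two-class design; "
            "use EcocSvm directly for k > 2"
        )
    T = class_epochs[0].shape[2]
    n_folds = config.n_sets
    preds = np.zeros((T, config.n_iterations, n_folds, 2), dtype=np.uint8)
    ss = np.random.SeedSequence(master)
    for i, child in enumerate(ss.spawn(config.n_iterations)):
        rng = np.random.default_rng(child)
        means, _ = make_averaged_sets(class_epochs, config.n_sets, rng)
        # (set, class, E, T) -> (T, set, class, E)
        m = np.ascontiguousarray(means.transpose(3, 0, 1, 2))
        for f in range(n_folds):
            train_sets = [s for s in range(n_folds) if s != f]
            # (T, 4, E): class 0's two training sets first, then class 1's
            train = np.ascontiguousarray(
                np.concatenate([m[:, train_sets, 0, :], m[:, train_sets, 1, :]], axis=1)
            )
            test = np.ascontiguousarray(m[:, f, :, :])  # (T, 2, E)
            preds[:, i, f, :] = decode_timepoints_binary(train, test, config.svm_C)
    raw, smoothed = accuracy_from_predictions(preds, config.smoothing_points)
    return AccuracyTimeSeries(
        subject=epochs.subject,
        times=ep.times,
        accuracy=smoothed,
        accuracy_raw=raw,
        predictions=preds,
        chance=config.chance,
        group=dict(epochs.group),
        smoothing_points=config.smoothing_points,
    )


def simulate_null_predictions(
    n_times: int = 275,
    n_iterations: int = 50,
    n_folds: int = 3,
    seed: int = 0,
    corr_sigma: float = 2.0,
    subject: str = "null_sim",
    group: dict | None = None,
    smoothing_points: int = 5,
    times: np.ndarray | None = None,
) -> AccuracyTimeSeries:
    """Synthetic decoder output under the null (labels carry no information).

    Each test exemplar's predicted class is the sign of a latent Gaussian
    process (white noise smoothed with a Gaussian kernel of ``corr_sigma``
    decoded samples), drawn independently of the true label — so marginal
    accuracy is 0.5 while predictions keep the temporal correlation the 30 Hz
    low-pass induces in real decoder output. Used to calibrate the
    family-wise error of the cluster permutation test at desk scale.
    """
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_times, n_iterations, n_folds, 2))
    if corr_sigma > 0:
        latent = gaussian_filter1d(latent, corr_sigma, axis=0)
    preds = (latent > 0).astype(np.uint8)
    raw, smoothed = accuracy_from_predictions(preds, smoothing_points)
    if times is None:
        times = -100.0 + 4.0 * np.arange(n_times)
    return AccuracyTimeSeries(
        subject=subject,
        times=times,
        accuracy=smoothed,
        accuracy_raw=raw,
        predictions=preds,
        chance=0.5,
        group=group or {},
        smoothing_points=smoothing_points,
    )
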