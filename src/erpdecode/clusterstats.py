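"""Group-level cluster-mass permutation inference on accuracy time series.

Three steps: (1) a one-sample t-test against chance at every decoded time
point (one-tailed: only above-chance decoding is meaningful); (2) maximal
runs of contiguous significant points form clusters scored by their t mass
(the sum of pointwise t values); (3) each observed mass is compared with a
null distribution of maximum cluster masses built by permuting at the
decoder-output stage — within each subject, the assignment of true labels to
the stored test-stage predictions is shuffled per fold × iteration (one swap
decision shared across time points, preserving each subject's temporal
correlation structure), the accuracy series is recomputed and smoothed
identically, and the pointwise-t/clustering steps are re-run. With two
classes a label swap simply flips the correctness of both attempts in a fold.

p-values use the +1 permutation correction and are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decoding import AccuracyTimeSeries, smooth_accuracy


@dataclass
class Cluster:
    start: int                 # decoded time-point index, inclusive
    end: int                   # inclusive
    t_mass: float
    p_value: float | None = None

    def times(self, time_axis) -> tuple[float, float]:
        return float(time_axis[self.start]), float(time_axis[self.end])


@dataclass
class PermutationNull:
    max_mass_distribution: np.ndarray
    n_permutations: int
    seed: int


def pointwise_t(accuracies: np.ndarray, chance: float = 0.5,
                tail: str = "greater"):
    """One-sample t against chance at each time point.

    ``accuracies`` is subjects × time. Returns (t, p, zero_variance mask).
    Zero-variance points get t = +inf (p = 0) if the mean is above chance,
    t = 0 (p = 0.5) at exactly chance, and t = -inf below; they are flagged
    so cluster formation can exclude them.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 2 or acc.shape[0] < 2:
        raise ValueError("need a subjects × time array with at least 2 subjects")
    n = acc.shape[0]
    mean = acc.mean(axis=0)
    sd = acc.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - chance) / (sd / np.sqrt(n))
    t[zero_var & (mean > chance)] = np.inf
    t[zero_var & (mean < chance)] = -np.inf
    t[zero_var & (mean == chance)] = 0.0
    if tail == "greater":
        p = stats.t.sf(t, n - 1)
    elif tail == "two-sided":
        p = 2 * stats.t.sf(np.abs(t), n - 1)
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    return t, p, zero_var


def form_clusters(mask: np.ndarray, t: np.ndarray) -> list[Cluster]:
    """Maximal runs of True in ``mask``, scored by the sum of ``t`` inside."""
    mask = np.asarray(mask, dtype=bool)
    t = np.asarray(t, dtype=float)
    if mask.shape != t.shape:
        raise ValueError("mask and t must be aligned")
    clusters: list[Cluster] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            clusters.append(Cluster(start, i - 1, float(t[start:i].sum())))
            start = None
    if start is not None:
        clusters.append(Cluster(start, len(mask) - 1, float(t[start:].sum())))
    return clusters


def max_cluster_mass(accuracies: np.ndarray, chance: float, alpha: float,
                     tail: str = "greater") -> float:
    """Largest cluster t mass of a subjects × time accuracy matrix (0 if none)."""
    t, p, zero_var = pointwise_t(accuracies, chance, tail)
    clusters = form_clusters((p < alpha) & ~zero_var, t)
    return max((c.t_mass for c in clusters), default=0.0)


def _fold_pair_accuracy(acc: AccuracyTimeSeries) -> np.ndarray:
    """Mean correctness per (time, iteration × fold) pair, in {0, ½, 1}."""
    preds = acc.predictions
    n_classes = preds.shape[-1]
    if n_classes != 2:
        raise NotImplementedError("output-stage permutation implemented for 2 classes")
    truth = np.arange(n_classes, dtype=preds.dtype)
    correct = (preds == truth).mean(axis=-1)      # (T, iter, fold)
    return correct.reshape(correct.shape[0], -1)  # (T, iter*fold)


def permutation_null(
    acc_list: list[AccuracyTimeSeries],
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    tail: str = "greater",
) -> PermutationNull:
    """Null distribution of maximum cluster t mass from stored decoder outputs.

    Requires every subject's per-attempt predictions. Deterministic in seed.
    """
    for a in acc_list:
        if a.predictions.size == 0:
            raise ValueError(f"subject {a.subject}: no stored decoder outputs")
    chance = acc_list[0].chance
    smooth_pts = acc_list[0].smoothing_points
    A = [_fold_pair_accuracy(a) for a in acc_list]     # per subject (T, IF)
    rng = np.random.default_rng(seed)
    n_sub = len(A)
    T = A[0].shape[0]
    masses = np.empty(n_permutations)
    acc_perm = np.empty((n_sub, T))
    for p in range(n_permutations):
        for s, a in enumerate(A):
            swap = rng.integers(0, 2, size=a.shape[1]).astype(float)
            # a binary-label swap flips both attempts' correctness in the fold
            series = (a @ (1.0 - swap) + (1.0 - a) @ swap) / a.shape[1]
            acc_perm[s] = smooth_accuracy(series, smooth_pts)
        masses[p] = max_cluster_mass(acc_perm, chance, alpha, tail)
    return PermutationNull(max_mass_distribution=masses,
                           n_permutations=n_permutations, seed=seed)


def cluster_pvalues(clusters: list[Cluster], null: PermutationNull) -> list[Cluster]:
    """Attach permutation p-values: p = (1 + #{null ≥ mass}) / (1 + n_perm)."""
    if null.n_permutations < 1:
        raise ValueError("empty permutation null")
    dist = null.max_mass_distribution
    for c in clusters:
        c.p_value = float((1 + np.sum(dist >= c.t_mass)) / (1 + null.n_permutations))
    return clusters


def cluster_test(
    acc_list: list[AccuracyTimeSeries],
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    tail: str = "greater",
    use_smoothed: bool = True,
):
    """Full observed-vs-permutation cluster analysis for one group.

    Returns (clusters with p-values, null, t values, significance mask).
    """
    acc = np.stack([a.accuracy if use_smoothed else a.accuracy_raw for a in acc_list])
    t, p, zero_var = pointwise_t(acc, acc_list[0].chance, tail)
    mask = (p < alpha) & ~zero_var
    clusters = form_clusters(mask, t)
    null = permutation_null(acc_list, n_permutations, seed, alpha, tail)
    return cluster_pvalues(clusters, null), null, t, mask
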