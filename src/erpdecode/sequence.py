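"""Pseudorandom oddball stimulus sequences.

A session consists of blocks of trials in which rare deviant targets are
embedded among two equally frequent types of standard stimuli (unambiguous
and ambiguous portraits). Ordering is constrained: a bounded number of
standards must separate consecutive deviants, and no more than a fixed number
of same-type standards may follow each other. Sequences are built by
constraint-aware sampling with rejection and an explicit retry budget, so an
unsatisfiable specification fails loudly rather than looping forever.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEVIANT = "deviant"
STANDARD_UNAMBIGUOUS = "standard_unambiguous"
STANDARD_AMBIGUOUS = "standard_ambiguous"
STANDARD_LABELS = (STANDARD_UNAMBIGUOUS, STANDARD_AMBIGUOUS)


class SequenceError(ValueError):
    """Raised when a sequence specification is invalid or unsatisfiable."""


@dataclass(frozen=True)
class SequenceSpec:
    """Structural parameters of one oddball session.

    Defaults reproduce the 6-block design: 80 trials per block, 8 deviants
    among 36 + 36 standards of the two types, 4-12 standards between
    consecutive deviants, runs of at most 3 same-type standards, 300 ms
    stimulus duration and 1500-1700 ms inter-stimulus intervals jittered in
    50 ms steps.
    """

    n_blocks: int = 6
    trials_per_block: int = 80
    deviants_per_block: int = 8
    min_standards_between_deviants: int = 4
    max_standards_between_deviants: int = 12
    max_same_type_run: int = 3
    stimulus_duration: float = 300.0
    isi_min: float = 1500.0
    isi_max: float = 1700.0
    isi_step: float = 50.0
    retry_budget: int = 10_000

    def __post_init__(self) -> None:
        if self.standards_per_block % 2:
            raise SequenceError(
                "standards per block must split evenly between the two types"
            )
        if self.isi_min > self.isi_max:
            raise SequenceError("isi_min must not exceed isi_max")
        if self.isi_max > self.isi_min:
            ratio = (self.isi_max - self.isi_min) / self.isi_step
            if abs(ratio - round(ratio)) > 1e-9:
                raise SequenceError("(isi_max - isi_min) must be divisible by isi_step")
        if self.min_standards_between_deviants > self.max_standards_between_deviants:
            raise SequenceError("deviant spacing bounds inverted")

    @property
    def standards_per_block(self) -> int:
        return self.trials_per_block - self.deviants_per_block

    @property
    def isi_grid(self) -> np.ndarray:
        n = int(round((self.isi_max - self.isi_min) / self.isi_step)) + 1 if self.isi_max > self.isi_min else 1
        return self.isi_min + self.isi_step * np.arange(n)


@dataclass
class TrialSequence:
    """Ordered stimulus labels with onsets for one session."""

    labels: list[str]
    onsets: np.ndarray          # ms from session start
    isis: np.ndarray            # ms, ISI following each trial
    block_index: np.ndarray     # 0-based block per trial
    spec: SequenceSpec = field(default_factory=SequenceSpec)

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": self.block_index,
                "trial": np.arange(len(self.labels)),
                "label": self.labels,
                "onset_ms": self.onsets,
                "isi_ms": self.isis,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, spec: SequenceSpec | None = None) -> "TrialSequence":
        df = pd.read_csv(path, sep="\t")
        return cls(
            labels=list(df["label"]),
            onsets=df["onset_ms"].to_numpy(float),
            isis=df["isi_ms"].to_numpy(float),
            block_index=df["block"].to_numpy(int),
            spec=spec or SequenceSpec(),
        )

    def counts(self) -> dict[str, int]:
        out = {DEVIANT: 0, STANDARD_UNAMBIGUOUS: 0, STANDARD_AMBIGUOUS: 0}
        for lab in self.labels:
            out[lab] += 1
        return out


def _place_deviants(spec: SequenceSpec, rng: np.random.Generator) -> np.ndarray | None:
    """Gap composition for one block: standards before/between/after deviants.

    Returns gaps ``g_0..g_d`` (length deviants+1) whose interior entries obey
    the spacing bounds, or None if the draw is infeasible.
    """
    d = spec.deviants_per_block
    total = spec.standards_per_block
    if d == 0:
        return np.array([total])
    inner = rng.integers(
        spec.min_standards_between_deviants,
        spec.max_standards_between_deviants + 1,
        size=d - 1,
    )
    rest = total - inner.sum()
    if rest < 0:
        return None
    g0 = rng.integers(0, rest + 1)
    return np.concatenate([[g0], inner, [rest - g0]])


def _assign_types(n_slots_runs: list[int], spec: SequenceSpec,
                  rng: np.random.Generator) -> list[str] | None:
    """Assign standard types over segments separated by deviants.

    A deviant interrupts a run, so the same-type-run constraint is enforced
    within each contiguous standard segment independently. Sequential
    sampling weighted by remaining counts; None on dead end.
    """
    remaining = {
        STANDARD_UNAMBIGUOUS: spec.standards_per_block // 2,
        STANDARD_AMBIGUOUS: spec.standards_per_block // 2,
    }
    out: list[list[str]] = []
    for seg_len in n_slots_runs:
        seg: list[str] = []
        run_type, run_len = None, 0
        for _ in range(seg_len):
            allowed = [
                t for t in STANDARD_LABELS
                if remaining[t] > 0 and not (t == run_type and run_len >= spec.max_same_type_run)
            ]
            if not allowed:
                return None
            weights = np.array([remaining[t] for t in allowed], float)
            choice = rng.choice(len(allowed), p=weights / weights.sum())
            t = allowed[int(choice)]
            remaining[t] -= 1
            if t == run_type:
                run_len += 1
            else:
                run_type, run_len = t, 1
            seg.append(t)
        out.append(seg)
    flat: list[str] = []
    for seg in out:
        flat.extend(seg)
        flat.append(DEVIANT)
    # one deviant between consecutive segments: drop the trailing one
    return flat[:-1]


def _build_block(spec: SequenceSpec, rng: np.random.Generator) -> list[str]:
    for _ in range(spec.retry_budget):
        gaps = _place_deviants(spec, rng)
        if gaps is None:
            continue
        labels = _assign_types(list(gaps), spec, rng)
        if labels is None:
            continue
        # _assign_types inserts a deviant between segments; gaps has d+1
        # segments so d deviants are inserted, giving trials_per_block labels.
        if len(labels) != spec.trials_per_block:  # pragma: no cover - guard
            raise SequenceError("internal: block length mismatch")
        return labels
    raise SequenceError(
        "could not satisfy deviant-spacing/run-length constraints within "
        f"retry budget of {spec.retry_budget}; check SequenceSpec feasibility"
    )


def generate_sequence(spec: SequenceSpec = SequenceSpec(), seed: int = 0) -> TrialSequence:
    """Generate a pseudorandom session satisfying all ordering constraints.

    Deterministic in ``seed``. Raises :class:`SequenceError` naming the
    violated constraint class if the spec is unsatisfiable within the retry
    budget.
    """
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    blocks: list[int] = []
    for b in range(spec.n_blocks):
        block = _build_block(spec, rng)
        labels.extend(block)
        blocks.extend([b] * len(block))
    n = len(labels)
    isis = rng.choice(spec.isi_grid, size=n)
    onsets = np.empty(n)
    t = 0.0
    for i in range(n):
        onsets[i] = t
        t += spec.stimulus_duration + isis[i]
    return TrialSequence(
        labels=labels,
        onsets=onsets,
        isis=isis,
        block_index=np.asarray(blocks),
        spec=spec,
    )


def check_sequence(seq: TrialSequence, spec: SequenceSpec | None = None) -> list[str]:
    """Independent constraint scanner; returns a list of violation messages.

    Deliberately shares no bookkeeping with the generator: it re-derives
    per-block counts, deviant spacing and same-type run lengths directly from
    the emitted labels.
    """
    spec = spec or seq.spec
    problems: list[str] = []
    labels = np.asarray(seq.labels)
    blocks = np.asarray(seq.block_index)
    grid = set(np.round(spec.isi_grid, 6))
    for isi in np.unique(np.round(seq.isis, 6)):
        if isi not in grid:
            problems.append(f"ISI {isi} ms off the jitter grid")
    for b in range(spec.n_blocks):
        lab = labels[blocks == b]
        if len(lab) != spec.trials_per_block:
            problems.append(f"block {b}: {len(lab)} trials")
        n_dev = int(np.sum(lab == DEVIANT))
        if n_dev != spec.deviants_per_block:
            problems.append(f"block {b}: {n_dev} deviants")
        for t in STANDARD_LABELS:
            if int(np.sum(lab == t)) != spec.standards_per_block // 2:
                problems.append(f"block {b}: unbalanced standard type {t}")
        # deviant spacing
        dev_pos = np.flatnonzero(lab == DEVIANT)
        for a, c in zip(dev_pos[:-1], dev_pos[1:]):
            gap = c - a - 1
            if not spec.min_standards_between_deviants <= gap <= spec.max_standards_between_deviants:
                problems.append(f"block {b}: deviant gap {gap}")
        # same-type runs (a deviant interrupts the run)
        run_type, run_len = None, 0
        for x in lab:
            if x == DEVIANT:
                run_type, run_len = None, 0
                continue
            if x == run_type:
                run_len += 1
            else:
                run_type, run_len = x, 1
            if run_len > spec.max_same_type_run:
                problems.append(f"block {b}: same-type run exceeds {spec.max_same_type_run}")
                run_len = 0
    return problems
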