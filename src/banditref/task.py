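"""Bandit-task structure: outcomes, block schedules, and trial-table I/O.

The task is a two-armed bandit played for 200 trials.  On every trial the
participant picks bandit A or B and sees one of three infant-face outcomes,
coded −1 (crying), 0 (neutral) or +1 (happy).  Each bandit has a latent
outcome-probability triple that switches every 40 trials, so the better
bandit changes over the session.  Two between-subject conditions differ only
in the baseline face shown before choice: ``soothe`` (crying baseline) and
``keep_happy`` (happy baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOMES",
    "OUTCOME_LABELS",
    "CONDITIONS",
    "BANDITS",
    "RewardSchedule",
    "TrialRecord",
    "SubjectDataset",
    "build_reward_schedule",
    "default_schedule",
    "sample_outcome",
    "read_trials",
    "write_trials",
]

OUTCOMES = (-1, 0, 1)
OUTCOME_LABELS = {-1: "crying", 0: "neutral", 1: "happy"}
CONDITIONS = ("soothe", "keep_happy")
BANDITS = ("A", "B")

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class RewardSchedule:
    """Per-block outcome probabilities for both bandits.

    ``probs`` has shape (n_blocks, 2, 3): axis 1 is bandit (A, B), axis 2 is
    the probability of outcome (−1, 0, +1).  Trial ``t`` is governed by
    block ``t // block_length`` (half-open block boundaries).
    """

    n_trials: int
    block_length: int
    probs: np.ndarray

    @property
    def n_blocks(self) -> int:
        return self.probs.shape[0]

    def block_of(self, trial_index: int) -> int:
        if not 0 <= trial_index < self.n_trials:
            raise IndexError(f"trial_index {trial_index} outside [0, {self.n_trials})")
        return trial_index // self.block_length

    def triple(self, trial_index: int, bandit: str) -> np.ndarray:
        return self.probs[self.block_of(trial_index), BANDITS.index(bandit)]


def build_reward_schedule(n_trials: int, block_length: int, block_probs) -> RewardSchedule:
    """Validate and assemble a :class:`RewardSchedule`.

    ``block_probs`` is a sequence of per-block pairs of outcome triples,
    ordered (bandit A triple, bandit B triple); each triple gives the
    probabilities of (−1, 0, +1) and must sum to 1.
    """
    if n_trials <= 0 or block_length <= 0:
        raise ValueError("n_trials and block_length must be positive")
    if n_trials % block_length != 0:
        raise ValueError(
            f"n_trials={n_trials} is not divisible by block_length={block_length}"
        )
    probs = np.asarray(block_probs, dtype=float)
    if probs.shape != (n_trials // block_length, 2, 3):
        raise ValueError(
            f"expected {n_trials // block_length} blocks of 2 bandit triples, "
            f"got shape {probs.shape}"
        )
    if np.any(probs < 0):
        raise ValueError("outcome probabilities must be non-negative")
    sums = probs.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > _PROB_TOL):
        bad = np.argwhere(np.abs(sums - 1.0) > _PROB_TOL)[0]
        raise ValueError(
            f"probability triple for block {bad[0]}, bandit {BANDITS[bad[1]]} "
            f"sums to {sums[tuple(bad)]!r}, not 1"
        )
    return RewardSchedule(n_trials=n_trials, block_length=block_length, probs=probs)


def default_schedule(n_trials: int = 200, block_length: int = 40) -> RewardSchedule:
    """Stand-in schedule: a good (0.1, 0.3, 0.6) and a bad (0.6, 0.3, 0.1)
    bandit whose identities swap every block, so the beneficial bandit
    changes over time while all three outcomes stay observable.  The
    nominal probabilities of the original task are not published; this
    default is configurable everywhere it is consumed.
    """
    good = (0.1, 0.3, 0.6)
    bad = (0.6, 0.3, 0.1)
    n_blocks = n_trials // block_length
    blocks = [
        (good, bad) if k % 2 == 0 else (bad, good) for k in range(n_blocks)
    ]
    return build_reward_schedule(n_trials, block_length, blocks)


def sample_outcome(
    schedule: RewardSchedule, trial_index: int, bandit: str, rng: np.random.Generator
) -> int:
    """Draw one outcome from the active block's triple for a bandit."""
    triple = schedule.triple(trial_index, bandit)
    return int(rng.choice(np.array(OUTCOMES), p=triple))


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    condition: str
    trial_index: int
    block_index: int
    choice: str
    outcome: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be in {CONDITIONS}, got {self.condition!r}")
        if self.choice not in BANDITS:
            raise ValueError(f"choice must be in {BANDITS}, got {self.choice!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be in {OUTCOMES}, got {self.outcome!r}")


@dataclass
class SubjectDataset:
    """One subject's ordered choice/outcome sequence with condition label."""

    subject_id: str
    condition: str
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [t.trial_index for t in self.trials]
        if idx != list(range(len(idx))):
            raise ValueError(
                f"subject {self.subject_id}: trials must be sorted 0..n-1 with no gaps"
            )

    def __len__(self) -> int:
        return len(self.trials)

    def choice_array(self) -> np.ndarray:
        """Choices as 0 (A) / 1 (B)."""
        return np.array([BANDITS.index(t.choice) for t in self.trials], dtype=np.int64)

    def outcome_array(self) -> np.ndarray:
        return np.array([t.outcome for t in self.trials], dtype=np.int64)

    def same_bandit_fraction(self) -> float:
        """Fraction of trials spent on the most-chosen bandit."""
        if not self.trials:
            return 0.0
        c = self.choice_array()
        return max(np.mean(c == 0), np.mean(c == 1))


_COLUMNS = ["subject_id", "condition", "trial", "block", "choice", "outcome"]


def write_trials(datasets: list[SubjectDataset], path) -> None:
    """Write subject datasets to long-format CSV (one row per trial)."""
    rows = [
        (d.subject_id, d.condition, t.trial_index, t.block_index, t.choice, t.outcome)
        for d in datasets
        for t in d.trials
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_trials(path) -> list[SubjectDataset]:
    """Read a long-format trials CSV back into :class:`SubjectDataset` lists.

    Raises ``ValueError`` naming the offending row on malformed input
    (missing column, outcome outside {−1, 0, 1}, duplicated trial).
    """
    df = pd.read_csv(Path(path), dtype={"subject_id": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials file {path} is missing columns {missing}")

    datasets: list[SubjectDataset] = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("trial")
        if grp["trial"].duplicated().any():
            dup = int(grp.loc[grp["trial"].duplicated(), "trial"].iloc[0])
            raise ValueError(f"subject {subject_id}: duplicate trial {dup}")
        conditions = grp["condition"].unique()
        if len(conditions) != 1:
            raise ValueError(f"subject {subject_id}: mixed condition labels {conditions}")
        trials = []
        for i, row in enumerate(grp.itertuples(index=False)):
            if row.outcome not in OUTCOMES:
                raise ValueError(
                    f"subject {subject_id}, trial {row.trial}: outcome {row.outcome!r} "
                    f"not in {OUTCOMES}"
                )
            trials.append(
                TrialRecord(
                    subject_id=str(subject_id),
                    condition=str(row.condition),
                    trial_index=int(row.trial),
                    block_index=int(row.block),
                    choice=str(row.choice),
                    outcome=int(row.outcome),
                )
            )
        datasets.append(SubjectDataset(str(subject_id), str(conditions[0]), trials))
    return datasets
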