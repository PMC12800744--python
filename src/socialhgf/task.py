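"""Synthetic advice-taking task schedules.

The task is a 170-trial binary lottery in which a participant combines a
non-social cue (a pie chart showing the winning probability of each option)
with the recommendation of an adviser who holds privileged but imperfect
information (accurate on 80% of trials).  The adviser's policy is helpful
throughout two stable phases (34 trials each) and alternates between helpful
and misleading in blocks during the intervening volatile phase (102 trials).

The generator is parametric: advice accuracy is assigned with exact
stratified counts per policy block, and the global number of trials on which
the adviser's privileged information matches the lottery outcome is pinned
exactly to ``round(privileged_accuracy * n_trials)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PHASE_LABELS = ("S1", "V", "S2")

__all__ = ["TaskConfig", "TaskSchedule", "make_schedule", "schedule_to_inputs"]


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the advice-taking task.

    Defaults reproduce the published design: 170 trials split 34/102/34,
    privileged adviser information accurate on 80% of trials, and rapid
    policy shifts (blocks of 10-20 trials) inside the volatile phase.
    """

    n_trials: int = 170
    phase_lengths: tuple[int, int, int] = (34, 102, 34)
    privileged_accuracy: float = 0.8
    helpful_advice_accuracy: float = 0.8
    misleading_advice_accuracy: float = 0.2
    volatile_block_length_range: tuple[int, int] = (10, 20)
    cue_prob_set: tuple[float, ...] = (0.25, 0.35, 0.45, 0.55, 0.65, 0.75)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.phase_lengths) != self.n_trials:
            raise ValueError(
                f"phase_lengths {self.phase_lengths} do not sum to "
                f"n_trials={self.n_trials}"
            )
        for name in ("privileged_accuracy", "helpful_advice_accuracy",
                     "misleading_advice_accuracy"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.misleading_advice_accuracy > self.helpful_advice_accuracy:
            raise ValueError(
                "misleading_advice_accuracy must not exceed "
                "helpful_advice_accuracy"
            )
        if len(self.cue_prob_set) == 0:
            raise ValueError("cue_prob_set must not be empty")
        if any(not 0.0 <= c <= 1.0 for c in self.cue_prob_set):
            raise ValueError("cue probabilities must lie in [0, 1]")
        lo, hi = self.volatile_block_length_range
        if not (1 <= lo <= hi):
            raise ValueError(
                f"invalid volatile_block_length_range {self.volatile_block_length_range}"
            )

    def with_seed(self, seed: int) -> "TaskConfig":
        return replace(self, seed=seed)


@dataclass
class TaskSchedule:
    """Per-trial task sequence.

    ``table`` holds one row per trial with columns ``trial`` (1-based),
    ``phase`` (S1/V/S2), ``policy`` (helpful/misleading), ``cue_prob``
    (pie-chart probability that the advised option wins),
    ``advice_accurate`` (u: did the advice match the lottery outcome) and
    ``lottery_outcome``.
    """

    table: pd.DataFrame
    config: TaskConfig = field(repr=False, default_factory=TaskConfig)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def u(self) -> np.ndarray:
        """Binary advice-accuracy sequence (the perceptual model's input)."""
        return self.table["advice_accurate"].to_numpy(dtype=np.float64)

    @property
    def c(self) -> np.ndarray:
        """Pie-chart probability of the advised option per trial."""
        return self.table["cue_prob"].to_numpy(dtype=np.float64)

    @property
    def phase(self) -> np.ndarray:
        return self.table["phase"].to_numpy()

    def phase_counts(self) -> tuple[int, int, int]:
        return tuple(int((self.table["phase"] == p).sum()) for p in PHASE_LABELS)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, config: TaskConfig | None = None) -> "TaskSchedule":
        table = pd.read_csv(path, sep="\t")
        return cls(table=table, config=config or TaskConfig())


def _volatile_blocks(rng: np.random.Generator, length: int,
                     block_range: tuple[int, int]) -> list[tuple[str, int]]:
    """Alternating policy blocks filling the volatile phase exactly."""
    lo, hi = block_range
    blocks: list[tuple[str, int]] = []
    remaining = length
    policy = "misleading"  # the phase transition itself is a policy change
    while remaining > 0:
        n = int(rng.integers(lo, hi + 1))
        n = min(n, remaining)
        blocks.append((policy, n))
        remaining -= n
        policy = "helpful" if policy == "misleading" else "misleading"
    return blocks


def make_schedule(config: TaskConfig | None = None) -> TaskSchedule:
    """Generate a seeded task schedule.

    Advice accuracy is assigned per policy block with exact counts
    (``round(rate * block length)`` accurate trials at random positions);
    afterwards single trials inside the volatile phase are flipped, if
    needed, so that the number of trials on which the adviser's privileged
    information matched the outcome equals
    ``round(privileged_accuracy * n_trials)`` exactly.  Privileged
    information is transmitted faithfully under the helpful policy and
    inverted under the misleading policy, so privileged-correct == u on
    helpful trials and == 1 - u on misleading trials.
    """
    if config is None:
        config = TaskConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    n_s1, n_v, n_s2 = config.phase_lengths

    phase = np.array(["S1"] * n_s1 + ["V"] * n_v + ["S2"] * n_s2)
    blocks: list[tuple[str, int]] = [("helpful", n_s1)]
    blocks += _volatile_blocks(rng, n_v, config.volatile_block_length_range)
    blocks.append(("helpful", n_s2))

    policy = np.empty(n, dtype=object)
    u = np.zeros(n, dtype=np.int64)
    pos = 0
    for pol, length in blocks:
        rate = (config.helpful_advice_accuracy if pol == "helpful"
                else config.misleading_advice_accuracy)
        n_acc = int(round(rate * length))
        idx = pos + rng.permutation(length)[:n_acc]
        u[idx] = 1
        policy[pos:pos + length] = pol
        pos += length

    # Pin the privileged-information accuracy exactly.
    helpful = policy == "helpful"
    priv_correct = np.where(helpful, u, 1 - u)
    target = int(round(config.privileged_accuracy * n))
    volatile = phase == "V"
    excess = int(priv_correct.sum()) - target
    while excess != 0:
        want = 0 if excess > 0 else 1  # priv_correct value we need more of
        candidates = np.flatnonzero(volatile & (priv_correct != want))
        if candidates.size == 0:  # fall back to stable phases
            candidates = np.flatnonzero(priv_correct != want)
        i = int(rng.choice(candidates))
        u[i] = 1 - u[i]
        priv_correct[i] = want
        excess += 1 if excess < 0 else -1

    cue_prob = rng.choice(np.asarray(config.cue_prob_set, dtype=float), size=n)
    lottery = rng.integers(0, 2, size=n)
    # advised option equals the outcome exactly on accurate-advice trials
    advised = np.where(u == 1, lottery, 1 - lottery)

    table = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "phase": phase,
            "policy": policy,
            "cue_prob": cue_prob,
            "advice_accurate": u,
            "lottery_outcome": lottery,
            "advised_option": advised,
        }
    )
    return TaskSchedule(table=table, config=config)


def schedule_to_inputs(schedule: TaskSchedule) -> np.ndarray:
    """Return the (u, c) pair sequence consumed by the filter, shape (n, 2)."""
    return np.column_stack([schedule.u, schedule.c])
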