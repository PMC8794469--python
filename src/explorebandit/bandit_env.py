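"""Restless two-armed bandit environment.

Each arm carries an independently drifting reward probability: on every
trial there is a fixed chance (default 10%) that an arm's probability steps
up or down by a fixed increment (default 0.10). Candidate walks are drawn
whole and rejected until they satisfy three criteria: the two arms' overall
means are within 2% of each other, probabilities never reach 0 or 1, and
there is no window of 30 consecutive trials with both arms below 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "RewardSchedule",
    "Session",
    "ScheduleGenerationError",
    "generate_reward_walk",
    "validate_schedule",
    "simulate_session",
    "chance_reward_rate",
]

#: reflecting bounds for the walk; a proposed step that would leave
#: [LOWER, UPPER] is rejected and the value stays, keeping probabilities on
#: the 0.1 grid implied by +/-10% steps.
LOWER_BOUND = 0.1
UPPER_BOUND = 0.9

MEAN_GAP_MAX = 0.02
LOW_REWARD_THRESHOLD = 0.20
LOW_REWARD_WINDOW = 30


class ScheduleGenerationError(RuntimeError):
    """Raised when no valid walk is found within the rejection budget."""


@dataclass(frozen=True)
class RewardSchedule:
    """Drifting per-arm reward probabilities for one session.

    ``p_reward`` has shape (n_trials, 2) with column 0 = left arm,
    column 1 = right arm.
    """

    n_trials: int
    p_reward: np.ndarray
    seed: Optional[int] = None
    step_prob: float = 0.10
    step_size: float = 0.10

    def __post_init__(self) -> None:
        p = np.asarray(self.p_reward, dtype=float)
        if p.shape != (self.n_trials, 2):
            raise ValueError(
                f"p_reward shape {p.shape} != ({self.n_trials}, 2)"
            )
        object.__setattr__(self, "p_reward", p)


@dataclass
class Session:
    """Per-trial record of one subject-session.

    Choices are coded 0 = left, 1 = right; rewards are 0/1. Latencies
    (seconds) and the generating schedule are optional so that real data
    without ground truth fits the same container.
    """

    subject_id: str
    group: str
    session_index: int
    choices: np.ndarray
    rewards: np.ndarray
    response_time: Optional[np.ndarray] = None
    retrieval_time: Optional[np.ndarray] = None
    schedule: Optional[RewardSchedule] = None

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int8)
        self.rewards = np.asarray(self.rewards, dtype=np.int8)
        if self.choices.shape != self.rewards.shape:
            raise ValueError("choices and rewards must have equal length")
        if not np.isin(self.choices, (0, 1)).all():
            raise ValueError("choices must be 0 (left) or 1 (right)")
        if not np.isin(self.rewards, (0, 1)).all():
            raise ValueError("rewards must be 0 or 1")
        if self.schedule is not None and self.schedule.n_trials != self.n_trials:
            raise ValueError("schedule length does not match session length")

    @property
    def n_trials(self) -> int:
        return int(self.choices.shape[0])


def _draw_candidate_walk(
    n_trials: int, step_prob: float, step_size: float, rng: np.random.Generator
) -> np.ndarray:
    """One unconstrained candidate walk (reflection at the bounds only)."""
    start_grid = np.arange(0.2, 0.8 + 1e-9, step_size)
    p = np.empty((n_trials, 2))
    p[0] = rng.choice(start_grid, size=2)
    steps = rng.random((n_trials - 1, 2)) < step_prob if n_trials > 1 else None
    signs = rng.integers(0, 2, size=(max(n_trials - 1, 0), 2)) * 2 - 1
    for t in range(1, n_trials):
        proposal = p[t - 1] + np.where(steps[t - 1], signs[t - 1] * step_size, 0.0)
        ok = (proposal >= LOWER_BOUND - 1e-9) & (proposal <= UPPER_BOUND + 1e-9)
        p[t] = np.where(ok, proposal, p[t - 1])
    return np.clip(p, LOWER_BOUND, UPPER_BOUND)


def validate_schedule(schedule: RewardSchedule) -> list[str]:
    """Check a schedule against the walk criteria.

    Returns an empty list iff all constraints hold; each violation string
    names the constraint and the first offending trial index (0-based).
    """
    p = schedule.p_reward
    violations: list[str] = []

    bad = np.where((p <= 0.0) | (p >= 1.0))[0]
    if bad.size:
        violations.append(
            f"probability outside (0, 1) at trial {int(bad[0])}"
        )

    if schedule.n_trials > 1:
        diffs = np.diff(p, axis=0)
        allowed = (
            np.isclose(diffs, 0.0, atol=1e-9)
            | np.isclose(np.abs(diffs), schedule.step_size, atol=1e-9)
        )
        bad = np.where(~allowed.all(axis=1))[0]
        if bad.size:
            violations.append(
                f"step not in {{0, +/-{schedule.step_size}}} at trial {int(bad[0]) + 1}"
            )

    gap = abs(p[:, 0].mean() - p[:, 1].mean())
    if gap > MEAN_GAP_MAX + 1e-12:
        violations.append(
            f"means differ by > {MEAN_GAP_MAX} (gap = {gap:.4f}, trial 0)"
        )

    both_low = (p < LOW_REWARD_THRESHOLD).all(axis=1).astype(int)
    if schedule.n_trials >= LOW_REWARD_WINDOW:
        window = np.convolve(both_low, np.ones(LOW_REWARD_WINDOW, dtype=int), "valid")
        bad = np.where(window == LOW_REWARD_WINDOW)[0]
        if bad.size:
            violations.append(
                f"{LOW_REWARD_WINDOW}-trial low-reward window starting at trial {int(bad[0])}"
            )
    return violations


def generate_reward_walk(
    n_trials: int = 300,
    step_prob: float = 0.10,
    step_size: float = 0.10,
    seed: Optional[int] = None,
    max_rejections: int = 10_000,
    constrained: bool = True,
) -> RewardSchedule:
    """Draw a valid restless-bandit reward schedule by rejection sampling.

    Whole candidate walks are drawn and discarded until all criteria hold.
    With ``constrained=False`` the first candidate is returned unchecked
    (useful for calibration of the raw step process).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < step_size < 0.5:
        raise ValueError("step_size must be in (0, 0.5)")
    if not 0.0 <= step_prob <= 1.0:
        raise ValueError("step_prob must be a probability")

    rng = np.random.default_rng(seed)
    last_violations: list[str] = []
    for _ in range(max_rejections):
        p = _draw_candidate_walk(n_trials, step_prob, step_size, rng)
        schedule = RewardSchedule(
            n_trials=n_trials,
            p_reward=p,
            seed=seed,
            step_prob=step_prob,
            step_size=step_size,
        )
        if not constrained:
            return schedule
        last_violations = validate_schedule(schedule)
        if not last_violations:
            return schedule
    raise ScheduleGenerationError(
        f"no valid walk within {max_rejections} candidates; "
        f"last candidate violated: {'; '.join(last_violations)}"
    )


Policy = Callable[[np.ndarray, np.ndarray], float]


def simulate_session(
    policy: Policy,
    schedule: RewardSchedule,
    seed: Optional[int] = None,
    subject_id: str = "sim",
    group: str = "sim",
    session_index: int = 1,
) -> Session:
    """Run a choice policy against a schedule.

    ``policy(choices_so_far, rewards_so_far)`` must return the probability
    of choosing arm 1 (right) on the next trial.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    choices = np.zeros(n, dtype=np.int8)
    rewards = np.zeros(n, dtype=np.int8)
    for t in range(n):
        p_right = float(policy(choices[:t], rewards[:t]))
        if not 0.0 <= p_right <= 1.0 or not np.isfinite(p_right):
            raise ValueError(
                f"policy returned {p_right!r} at trial {t}; must be in [0, 1]"
            )
        c = int(rng.random() < p_right)
        r = int(rng.random() < schedule.p_reward[t, c])
        choices[t] = c
        rewards[t] = r
    return Session(
        subject_id=subject_id,
        group=group,
        session_index=session_index,
        choices=choices,
        rewards=rewards,
        schedule=schedule,
    )


def chance_reward_rate(schedule: RewardSchedule) -> float:
    """Expected reward rate of a uniformly random chooser: the grand mean
    of the two arms' per-trial probabilities."""
    return float(schedule.p_reward.mean())
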