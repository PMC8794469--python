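"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from explorebandit.bandit_env import RewardSchedule, Session
from explorebandit.explore_hmm import HmmSpec, build_transition_matrix


def make_session(choices, rewards=None, schedule=None, **kwargs):
    choices = np.asarray(choices)
    if rewards is None:
        rewards = np.zeros_like(choices)
    defaults = dict(subject_id="s1", group="G", session_index=1)
    defaults.update(kwargs)
    return Session(
        choices=choices, rewards=np.asarray(rewards), schedule=schedule, **defaults
    )


def constant_schedule(p_left, p_right, n_trials):
    p = np.tile([p_left, p_right], (n_trials, 1))
    return RewardSchedule(n_trials=n_trials, p_reward=p)


def enumerate_path_probs(spec: HmmSpec, session: Session) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive oracle: probability of every latent path starting in
    explore, for sessions of modest length. Returns (paths, probs)."""
    T = session.n_trials
    emis = np.empty((T, 3))
    emis[:, 0] = 0.5
    emis[:, 1] = session.choices == 0
    emis[:, 2] = session.choices == 1
    paths = np.array(list(itertools.product(range(3), repeat=T)), dtype=int)
    paths = paths[paths[:, 0] == 0]
    probs = emis[0, paths[:, 0]].astype(float)
    for t in range(1, T):
        if spec.variant == "io4":
            A = build_transition_matrix(spec, int(session.rewards[t - 1]))
        else:
            A = build_transition_matrix(spec)
        probs = probs * A[paths[:, t - 1], paths[:, t]] * emis[t, paths[:, t]]
    return paths, probs


def brute_force_loglik(spec: HmmSpec, session: Session) -> float:
    _, probs = enumerate_path_probs(spec, session)
    return float(np.log(probs.sum()))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
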