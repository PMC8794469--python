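"""Seven reinforcement-learning choice models and their maximum-likelihood
fits.

Model roster (parameters in brackets):

* ``random`` [b] — constant side bias, P(left) = b.
* ``wsls`` [eps] — noisy win-stay/lose-shift: stay probability 1 - eps/2
  after a win, eps/2 after a loss.
* ``rl`` [alpha, beta] — delta-rule value learning with softmax choice.
* ``rl_eps`` [alpha, beta, eps] — softmax plus a value-independent lapse,
  P = eps + (1 - 2 eps) * softmax.
* ``rlck`` [alpha, beta, alpha_c, beta_c] — values plus a choice kernel
  (outcome-independent perseveration trace) combined in the softmax.
* ``rlck_gamma`` [.. gamma] — rlck with learning rate gamma * alpha on
  unrewarded trials (asymmetric learning).
* ``rlck_eta`` [.. eta] — rlck with a mixing weight eta between the value
  and the choice-kernel contributions.

Q values start at 0.5 per arm and choice kernels at 0; both reset at every
session boundary. Only the chosen arm's Q updates; the kernel updates for
every arm toward its chosen indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from . import _kernels
from .bandit_env import RewardSchedule, Session, generate_reward_walk, simulate_session
from .explore_hmm import StateSequence, fit_hmm, viterbi_decode

__all__ = [
    "MODEL_IDS",
    "PARAM_BOUNDS",
    "RlFit",
    "LatentTrace",
    "rl_nll",
    "fit_rl",
    "model_agreement",
    "rl_explore_labels",
    "make_policy",
    "exploration_grid_experiment",
    "exploration_glm",
]

_MODEL_CODES = {
    "random": _kernels.M_RANDOM,
    "wsls": _kernels.M_WSLS,
    "rl": _kernels.M_RL,
    "rl_eps": _kernels.M_RL_EPS,
    "rlck": _kernels.M_RLCK,
    "rlck_gamma": _kernels.M_RLCK_GAMMA,
    "rlck_eta": _kernels.M_RLCK_ETA,
}
MODEL_IDS = tuple(_MODEL_CODES)

MODEL_PARAMS = {
    "random": ("b",),
    "wsls": ("eps",),
    "rl": ("alpha", "beta"),
    "rl_eps": ("alpha", "beta", "eps"),
    "rlck": ("alpha", "beta", "alpha_c", "beta_c"),
    "rlck_gamma": ("alpha", "beta", "alpha_c", "beta_c", "gamma"),
    "rlck_eta": ("alpha", "beta", "alpha_c", "beta_c", "eta"),
}

PARAM_BOUNDS = {
    "b": (0.0, 1.0),
    "eps": (0.0, 0.5),
    "alpha": (0.0, 1.0),
    "beta": (0.0, 20.0),
    "alpha_c": (0.0, 1.0),
    "beta_c": (0.0, 20.0),
    "gamma": (0.0, 2.0),
    "eta": (0.0, 1.0),
}

# slot order expected by the kernel
_SLOTS = ("b", "eps", "alpha", "beta", "alpha_c", "beta_c", "gamma", "eta")


@dataclass
class LatentTrace:
    """Per-trial latent quantities under one parameterization."""

    q: np.ndarray  # (T, 2) values in use on each trial
    ck: np.ndarray  # (T, 2) choice-kernel values in use on each trial
    p_right: np.ndarray  # (T,) P(choose arm 1)

    @property
    def p_chosen(self) -> np.ndarray:
        raise AttributeError("needs choices; use choice_probabilities")

    def choice_probabilities(self, choices: np.ndarray) -> np.ndarray:
        choices = np.asarray(choices)
        return np.where(choices == 1, self.p_right, 1.0 - self.p_right)


@dataclass
class RlFit:
    """Maximum-likelihood fit of one model to one unit (subject or
    session)."""

    model_id: str
    params: dict
    nll: float
    aic: float
    bic: float
    n_restarts: int
    seed: Optional[int]
    fit_unit: str = "subject"
    agreement: Optional[float] = None
    converged: bool = True
    subject_id: Optional[str] = None
    group: Optional[str] = None


def _check_params(model_id: str, params: dict) -> None:
    expected = MODEL_PARAMS[model_id]
    if set(params) != set(expected):
        raise ValueError(
            f"{model_id} requires params {list(expected)}, got {sorted(params)}"
        )
    for name, value in params.items():
        lo, hi = PARAM_BOUNDS[name]
        if not lo <= value <= hi:
            raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
    if model_id == "rlck_gamma" and params["gamma"] * params["alpha"] > 1.0 + 1e-12:
        raise ValueError("rlck_gamma requires gamma * alpha <= 1")


def _pack(model_id: str, params: dict) -> np.ndarray:
    vec = np.zeros(len(_SLOTS))
    for i, name in enumerate(_SLOTS):
        vec[i] = params.get(name, 0.0)
    return vec


def _concat_sessions(
    sessions: Union[Session, Sequence[Session]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[Session]]:
    if isinstance(sessions, Session):
        sessions = [sessions]
    sessions = list(sessions)
    if not sessions:
        raise ValueError("at least one session required")
    choices = np.concatenate([s.choices for s in sessions]).astype(np.int8)
    rewards = np.concatenate([s.rewards for s in sessions]).astype(np.int8)
    starts = np.cumsum([0] + [s.n_trials for s in sessions[:-1]]).astype(np.int64)
    return choices, rewards, starts, sessions


def rl_nll(
    model_id: str,
    params: dict,
    sessions: Union[Session, Sequence[Session]],
    return_trace: bool = False,
) -> Union[float, tuple[float, LatentTrace]]:
    """Negative log-likelihood (nats) of the observed choices, with Q/CK
    reset at each session start. Optionally returns the latent trace."""
    _check_params(model_id, params)
    choices, rewards, starts, _ = _concat_sessions(sessions)
    p_right, q, ck = _kernels.rl_trial_probs(
        _MODEL_CODES[model_id], _pack(model_id, params), choices, rewards, starts
    )
    nll = float(_kernels.nll_from_probs(p_right, choices))
    if return_trace:
        return nll, LatentTrace(q=q, ck=ck, p_right=p_right)
    return nll


def _objective(model_id: str, choices, rewards, starts):
    code = _MODEL_CODES[model_id]
    names = MODEL_PARAMS[model_id]

    def fun(x: np.ndarray) -> float:
        params = dict(zip(names, x))
        if model_id == "rlck_gamma" and params["gamma"] * params["alpha"] > 1.0:
            # smooth penalty pushing back into the feasible wedge
            excess = params["gamma"] * params["alpha"] - 1.0
            return 1e6 * (1.0 + excess)
        p_right, _, _ = _kernels.rl_trial_probs(
            code, _pack(model_id, params), choices, rewards, starts
        )
        return float(_kernels.nll_from_probs(p_right, choices))

    return fun


def fit_rl(
    model_id: str,
    sessions: Union[Session, Sequence[Session]],
    n_restarts: int = 10,
    seed: Optional[int] = None,
    fit_unit: str = "subject",
    subject_id: Optional[str] = None,
    group: Optional[str] = None,
) -> Union[RlFit, list[RlFit]]:
    """Bounded maximum-likelihood fit, best of ``n_restarts`` random
    initializations (L-BFGS-B).

    ``fit_unit='subject'`` pools all sessions into one fit with per-session
    resets; ``fit_unit='session'`` fits each session separately and returns
    a list (used for the session-by-session meta-learning analysis).
    """
    if fit_unit not in ("subject", "session"):
        raise ValueError("fit_unit must be 'subject' or 'session'")
    if isinstance(sessions, Session):
        sessions = [sessions]
    sessions = list(sessions)
    if fit_unit == "session":
        rng = np.random.default_rng(seed)
        return [
            fit_rl(
                model_id,
                [sess],
                n_restarts=n_restarts,
                seed=int(rng.integers(0, 2**31 - 1)),
                fit_unit="subject",
                subject_id=subject_id,
                group=group,
            )
            for sess in sessions
        ]

    choices, rewards, starts, sessions = _concat_sessions(sessions)
    names = MODEL_PARAMS[model_id]
    bounds = [PARAM_BOUNDS[p] for p in names]
    fun = _objective(model_id, choices, rewards, starts)
    rng = np.random.default_rng(seed)
    best_x, best_nll, converged = None, np.inf, False
    for _ in range(n_restarts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        if model_id == "rlck_gamma":
            i_a, i_g = names.index("alpha"), names.index("gamma")
            if x0[i_g] * x0[i_a] > 1.0:
                x0[i_g] = rng.uniform(0.0, 1.0 / max(x0[i_a], 1e-6))
        res = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_nll:
            best_x, best_nll = res.x, float(res.fun)
            converged = bool(res.success)
    params = dict(zip(names, (float(v) for v in best_x)))
    n_obs = len(choices)
    k = len(names)
    fit = RlFit(
        model_id=model_id,
        params=params,
        nll=best_nll,
        aic=2 * k + 2 * best_nll,
        bic=k * np.log(n_obs) + 2 * best_nll,
        n_restarts=n_restarts,
        seed=seed,
        fit_unit=fit_unit,
        converged=converged,
        subject_id=subject_id if subject_id is not None else sessions[0].subject_id,
        group=group if group is not None else sessions[0].group,
    )
    fit.agreement = model_agreement(fit, sessions)
    return fit


def model_agreement(
    fit: RlFit, sessions: Union[Session, Sequence[Session]]
) -> float:
    """Fraction of trials where the model's higher-probability arm matches
    the observed choice (ties earn half credit)."""
    choices, rewards, starts, _ = _concat_sessions(sessions)
    p_right, _, _ = _kernels.rl_trial_probs(
        _MODEL_CODES[fit.model_id], _pack(fit.model_id, fit.params), choices, rewards, starts
    )
    predicted_right = p_right > 0.5
    hits = (predicted_right == (choices == 1)).astype(float)
    hits[np.isclose(p_right, 0.5)] = 0.5
    return float(hits.mean())


def rl_explore_labels(
    fit: RlFit, sessions: Union[Session, Sequence[Session]]
) -> np.ndarray:
    """Binary explore labels in the value-deviation tradition: a trial is
    exploratory (1) iff the chosen arm's decision variable is strictly
    below the unchosen arm's (i.e. the modeled choice probability of the
    chosen arm is < 0.5); ties count as exploit."""
    if fit.model_id in ("random", "wsls"):
        raise ValueError(f"{fit.model_id} has no value trace to deviate from")
    choices, rewards, starts, _ = _concat_sessions(sessions)
    p_right, _, _ = _kernels.rl_trial_probs(
        _MODEL_CODES[fit.model_id], _pack(fit.model_id, fit.params), choices, rewards, starts
    )
    p_chosen = np.where(choices == 1, p_right, 1.0 - p_right)
    return (p_chosen < 0.5 - 1e-12).astype(np.int8)


def make_policy(model_id: str, params: dict):
    """Wrap a model as a ``policy(choices, rewards) -> P(right)`` callable
    for :func:`explorebandit.bandit_env.simulate_session`."""
    _check_params(model_id, params)
    code = _MODEL_CODES[model_id]
    vec = _pack(model_id, params)

    def policy(choices: np.ndarray, rewards: np.ndarray) -> float:
        t = len(choices)
        c = np.concatenate([choices, [0]]).astype(np.int8)
        r = np.concatenate([rewards, [0]]).astype(np.int8)
        p_right, _, _ = _kernels.rl_trial_probs(
            code, vec, c, r, np.zeros(1, dtype=np.int64)
        )
        return float(p_right[t])

    return policy


def exploration_grid_experiment(
    n_agents: int = 10_000,
    alpha_range: tuple[float, float] = (0.05, 1.0),
    beta_range: tuple[float, float] = (0.1, 10.0),
    trials: int = 300,
    seed: Optional[int] = None,
    hmm_restarts: int = 5,
) -> pd.DataFrame:
    """Simulate two-parameter RL agents across random (alpha, beta)
    combinations, label their choices with the tied HMM, and tabulate the
    probability of exploration and the obtained reward rate per agent.

    Learning rates are drawn uniformly; inverse temperatures are drawn
    log-uniformly over their range (beta is a scale parameter, so a log
    draw covers the high- and low-noise regimes evenly)."""
    if alpha_range[0] <= 0 or beta_range[0] <= 0:
        raise ValueError("ranges must be positive")
    rng = np.random.default_rng(seed)
    log_beta = (np.log(beta_range[0]), np.log(beta_range[1]))
    rows = []
    for agent in range(n_agents):
        alpha = float(rng.uniform(*alpha_range))
        beta = float(np.exp(rng.uniform(*log_beta)))
        try:
            schedule = generate_reward_walk(
                n_trials=trials, seed=int(rng.integers(0, 2**31 - 1))
            )
            sess = simulate_session(
                make_policy("rl", {"alpha": alpha, "beta": beta}),
                schedule,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            fit = fit_hmm(
                sess,
                "tied2",
                n_restarts=hmm_restarts,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            states = viterbi_decode(fit.spec, sess)
            rows.append(
                {
                    "agent": agent,
                    "alpha": alpha,
                    "beta": beta,
                    "p_explore": float(states.binary_explore.mean()),
                    "reward_rate": float(sess.rewards.mean()),
                }
            )
        except Exception:  # keep the grid alive on isolated agent failures
            rows.append(
                {
                    "agent": agent,
                    "alpha": alpha,
                    "beta": beta,
                    "p_explore": np.nan,
                    "reward_rate": np.nan,
                }
            )
    return pd.DataFrame(rows)


def exploration_glm(grid_table: pd.DataFrame) -> pd.DataFrame:
    """OLS of per-agent explore fraction on z-scored learning rate,
    z-scored inverse temperature, and their product. Returns coefficients
    with Wald p-values (rows: beta, alpha, interaction, const)."""
    table = grid_table.dropna(subset=["p_explore"])
    if table.empty:
        raise ValueError("empty grid table")
    z_alpha = table["alpha"].to_numpy(dtype=float)
    z_beta = table["beta"].to_numpy(dtype=float)
    for name, z in (("alpha", z_alpha), ("beta", z_beta)):
        if np.std(z) == 0:
            raise ValueError(f"degenerate (constant) predictor {name}")
    z_alpha = (z_alpha - z_alpha.mean()) / z_alpha.std()
    z_beta = (z_beta - z_beta.mean()) / z_beta.std()
    X = sm.add_constant(
        pd.DataFrame(
            {"beta": z_beta, "alpha": z_alpha, "interaction": z_alpha * z_beta}
        )
    )
    model = sm.OLS(table["p_explore"].to_numpy(dtype=float), X).fit()
    return pd.DataFrame(
        {"coef": model.params, "p_value": model.pvalues, "se": model.bse}
    )
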