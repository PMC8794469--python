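"""Explore/exploit labeling with discrete hidden Markov models.

The core model has three latent states — explore, exploit-left,
exploit-right — but only two free parameters: the probability of repeating
exploration (``a``) and of repeating exploitation (``d``), tied across the
two exploit states. Explore emits either arm uniformly; an exploit state
emits only its own arm. A switch between exploited arms must pass through
exploration, and every session is assumed to start in the explore state
(the initial distribution is fixed, not estimated).

Two four-parameter variants relax the core model: ``io4`` conditions the
stay probabilities on the previous trial's reward outcome (an input-output
HMM), and ``nt4`` removes the parameter tying so each exploit state has its
own entry and stay probability.

Fitting is expectation-maximization (Baum-Welch) with random restarts;
decoding is Viterbi with ties broken toward explore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _kernels
from .bandit_env import Session

__all__ = [
    "HmmSpec",
    "HmmFit",
    "StateSequence",
    "build_transition_matrix",
    "hmm_loglik",
    "fit_hmm",
    "viterbi_decode",
    "information_criteria",
    "explore_fraction",
    "simulate_tied_hmm",
    "STATE_NAMES",
]

STATE_EXPLORE, STATE_EXPLOIT_L, STATE_EXPLOIT_R = 0, 1, 2
STATE_NAMES = ("explore", "exploit_L", "exploit_R")
STATE_CODES = ("E", "L", "R")

_VARIANT_PARAMS = {
    "tied2": ("a", "d"),
    "io4": ("a_win", "a_loss", "d_win", "d_loss"),
    "nt4": ("q_L", "q_R", "d_L", "d_R"),
}


@dataclass(frozen=True)
class HmmSpec:
    """A model variant plus its transition parameters."""

    variant: str
    params: dict
    n_arms: int = 2

    def __post_init__(self) -> None:
        if self.variant not in _VARIANT_PARAMS:
            raise ValueError(f"unknown variant {self.variant!r}")
        expected = set(_VARIANT_PARAMS[self.variant])
        if set(self.params) != expected:
            raise ValueError(
                f"{self.variant} requires params {sorted(expected)}, "
                f"got {sorted(self.params)}"
            )
        for name, value in self.params.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"parameter {name}={value} outside [0, 1]")
        if self.variant == "nt4" and self.params["q_L"] + self.params["q_R"] > 1.0 + 1e-12:
            raise ValueError("nt4 requires q_L + q_R <= 1")

    @property
    def n_free_params(self) -> int:
        return len(_VARIANT_PARAMS[self.variant])


@dataclass
class HmmFit:
    """Best-of-restarts EM fit for one subject."""

    spec: HmmSpec
    total_loglik: float
    per_session_loglik: list[float]
    n_free_params_per_subject: int
    n_restarts: int
    best_seed: Optional[int]
    converged: bool
    n_iterations: int
    subject_id: Optional[str] = None
    group: Optional[str] = None
    loglik_trace: list[float] = field(default_factory=list)


@dataclass
class StateSequence:
    """Decoded per-trial latent states (integer codes 0/1/2)."""

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)

    @property
    def labels(self) -> np.ndarray:
        return np.array([STATE_NAMES[s] for s in self.states])

    @property
    def codes(self) -> np.ndarray:
        return np.array([STATE_CODES[s] for s in self.states])

    @property
    def binary_explore(self) -> np.ndarray:
        """1 where the trial is labeled explore, 0 where exploit."""
        return (self.states == STATE_EXPLORE).astype(np.int8)

    def __len__(self) -> int:
        return len(self.states)


def _tied2_matrix(a: float, d: float) -> np.ndarray:
    return np.array(
        [
            [a, (1 - a) / 2, (1 - a) / 2],
            [1 - d, d, 0.0],
            [1 - d, 0.0, d],
        ]
    )


def build_transition_matrix(
    spec: HmmSpec, prev_reward: Optional[int] = None
) -> np.ndarray:
    """3x3 row-stochastic transition matrix (rows/cols: explore,
    exploit_L, exploit_R). ``prev_reward`` is required iff variant is io4,
    selecting the win or loss matrix."""
    if spec.variant == "tied2":
        return _tied2_matrix(spec.params["a"], spec.params["d"])
    if spec.variant == "io4":
        if prev_reward not in (0, 1):
            raise ValueError("io4 requires prev_reward in {0, 1}")
        if prev_reward == 1:
            return _tied2_matrix(spec.params["a_win"], spec.params["d_win"])
        return _tied2_matrix(spec.params["a_loss"], spec.params["d_loss"])
    # nt4
    q_l, q_r = spec.params["q_L"], spec.params["q_R"]
    d_l, d_r = spec.params["d_L"], spec.params["d_R"]
    return np.array(
        [
            [1 - q_l - q_r, q_l, q_r],
            [1 - d_l, d_l, 0.0],
            [1 - d_r, 0.0, d_r],
        ]
    )


def _emissions(choices: np.ndarray) -> np.ndarray:
    c = np.asarray(choices)
    emis = np.empty((c.shape[0], 3))
    emis[:, 0] = 0.5
    emis[:, 1] = (c == 0).astype(float)
    emis[:, 2] = (c == 1).astype(float)
    return emis


def _trans_stack_and_classes(
    spec: HmmSpec, session: Session
) -> tuple[np.ndarray, np.ndarray]:
    T = session.n_trials
    if spec.variant == "io4":
        stack = np.stack(
            [build_transition_matrix(spec, 0), build_transition_matrix(spec, 1)]
        )
        classes = np.asarray(session.rewards[: max(T - 1, 0)], dtype=np.int64)
    else:
        stack = build_transition_matrix(spec)[None, :, :]
        classes = np.zeros(max(T - 1, 0), dtype=np.int64)
    return stack, classes


def hmm_loglik(spec: HmmSpec, session: Session) -> float:
    """Forward-algorithm log-likelihood (nats) of a session's choices."""
    if session.n_trials < 1:
        raise ValueError("session must have at least one trial")
    stack, classes = _trans_stack_and_classes(spec, session)
    ll, _ = _kernels.hmm_forward(_emissions(session.choices), stack, classes)
    return float(ll)


def viterbi_decode(spec: HmmSpec, session: Session) -> StateSequence:
    """Most probable a posteriori state path, trial 1 fixed to explore.
    Ties break toward the explore state."""
    stack, classes = _trans_stack_and_classes(spec, session)
    path = _kernels.hmm_viterbi(_emissions(session.choices), stack, classes)
    return StateSequence(path)


def _init_spec(variant: str, rng: np.random.Generator) -> HmmSpec:
    u = lambda: float(rng.uniform(0.5, 0.99))
    if variant == "tied2":
        return HmmSpec("tied2", {"a": u(), "d": u()})
    if variant == "io4":
        return HmmSpec(
            "io4", {"a_win": u(), "a_loss": u(), "d_win": u(), "d_loss": u()}
        )
    stay = u()
    v = float(rng.uniform(0.0, 1.0))
    return HmmSpec(
        "nt4",
        {"q_L": (1 - stay) * v, "q_R": (1 - stay) * (1 - v), "d_L": u(), "d_R": u()},
    )


def _ratio(num: float, den: float, fallback: float) -> float:
    if den <= 0.0:
        return fallback
    return min(max(num / den, 0.0), 1.0)


def _m_step(variant: str, xi: np.ndarray, old: dict) -> dict:
    """Closed-form M-step from pooled expected transition counts.
    Emissions and the initial distribution are fixed, so only the
    transition parameters update."""
    if variant == "tied2":
        row_e = xi[0, 0, :].sum()
        row_x = xi[0, 1, :].sum() + xi[0, 2, :].sum()
        return {
            "a": _ratio(xi[0, 0, 0], row_e, old["a"]),
            "d": _ratio(xi[0, 1, 1] + xi[0, 2, 2], row_x, old["d"]),
        }
    if variant == "io4":
        out = {}
        for cls, tag in ((0, "loss"), (1, "win")):
            row_e = xi[cls, 0, :].sum()
            row_x = xi[cls, 1, :].sum() + xi[cls, 2, :].sum()
            out[f"a_{tag}"] = _ratio(xi[cls, 0, 0], row_e, old[f"a_{tag}"])
            out[f"d_{tag}"] = _ratio(
                xi[cls, 1, 1] + xi[cls, 2, 2], row_x, old[f"d_{tag}"]
            )
        return out
    row_e = xi[0, 0, :].sum()
    q_l = _ratio(xi[0, 0, 1], row_e, old["q_L"])
    q_r = _ratio(xi[0, 0, 2], row_e, old["q_R"])
    if q_l + q_r > 1.0:  # numerical guard; expected counts already sum <= row
        total = q_l + q_r
        q_l, q_r = q_l / total, q_r / total
    return {
        "q_L": q_l,
        "q_R": q_r,
        "d_L": _ratio(xi[0, 1, 1], xi[0, 1, :].sum(), old["d_L"]),
        "d_R": _ratio(xi[0, 2, 2], xi[0, 2, :].sum(), old["d_R"]),
    }


def _em_once(
    variant: str,
    sessions: Sequence[Session],
    init: HmmSpec,
    tol: float,
    max_iter: int,
) -> tuple[HmmSpec, float, list[float], bool, int, list[float]]:
    spec = init
    prev_ll = -np.inf
    per_session: list[float] = []
    converged = False
    iteration = 0
    trace: list[float] = []
    emissions = [_emissions(s.choices) for s in sessions]
    for iteration in range(1, max_iter + 1):
        total = 0.0
        xi_acc: Optional[np.ndarray] = None
        per_session = []
        for sess, emis in zip(sessions, emissions):
            stack, classes = _trans_stack_and_classes(spec, sess)
            ll, xi = _kernels.hmm_forward_backward(emis, stack, classes)
            total += ll
            per_session.append(float(ll))
            xi_acc = xi if xi_acc is None else xi_acc + xi
        trace.append(float(total))
        if total - prev_ll < tol and iteration > 1:
            converged = total >= prev_ll - 1e-9
            prev_ll = max(total, prev_ll)
            break
        prev_ll = total
        spec = HmmSpec(variant, _m_step(variant, xi_acc, spec.params))
    return spec, float(prev_ll), per_session, converged, iteration, trace


def fit_hmm(
    sessions: Union[Session, Sequence[Session]],
    variant: str = "tied2",
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: Optional[int] = None,
    subject_id: Optional[str] = None,
    group: Optional[str] = None,
) -> HmmFit:
    """Fit one subject's sessions by Baum-Welch with random restarts.

    Each restart draws stay parameters uniform(0.5, 0.99), runs EM until
    the observed-data log-likelihood improves by less than ``tol`` nats,
    and the best restart (highest log-likelihood) is returned.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    if len(sessions) == 0:
        raise ValueError("at least one session required")
    if variant not in _VARIANT_PARAMS:
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        restart_seed = int(rng.integers(0, 2**31 - 1))
        init = _init_spec(variant, np.random.default_rng(restart_seed))
        spec, ll, per_sess, converged, n_iter, trace = _em_once(
            variant, sessions, init, tol, max_iter
        )
        if best is None or ll > best[1]:
            best = (spec, ll, per_sess, converged, n_iter, restart_seed, trace)
    spec, ll, per_sess, converged, n_iter, best_seed, trace = best
    if subject_id is None:
        subject_id = sessions[0].subject_id
    if group is None:
        group = sessions[0].group
    return HmmFit(
        spec=spec,
        total_loglik=ll,
        per_session_loglik=per_sess,
        n_free_params_per_subject=spec.n_free_params,
        n_restarts=n_restarts,
        best_seed=best_seed,
        converged=converged,
        n_iterations=n_iter,
        subject_id=subject_id,
        group=group,
        loglik_trace=trace,
    )


def _fit_key_loglik_k(fit) -> tuple[str, float, int]:
    if isinstance(fit, tuple):
        label, loglik, k = fit
        return str(label), float(loglik), int(k)
    if isinstance(fit, HmmFit):
        return fit.spec.variant, fit.total_loglik, fit.n_free_params_per_subject
    # duck-typed RlFit
    return fit.model_id, -fit.nll, len(fit.params)


def information_criteria(fits: Sequence, n_obs: int) -> pd.DataFrame:
    """AIC/BIC model-comparison table from per-subject fits.

    Fits sharing a model identifier are pooled: log-likelihoods sum and
    the free-parameter count is params-per-subject times the number of
    subjects. ``(label, loglik, k)`` tuples are also accepted. Relative
    likelihood of model m versus the best model is exp((IC_best - IC_m)/2).
    """
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    pooled: dict[str, list[float]] = {}
    for fit in fits:
        key, loglik, k = _fit_key_loglik_k(fit)
        agg = pooled.setdefault(key, [0.0, 0])
        agg[0] += loglik
        agg[1] += k
    rows = []
    for key, (loglik, k) in pooled.items():
        aic = 2 * k - 2 * loglik
        bic = k * math.log(n_obs) - 2 * loglik
        rows.append({"model": key, "loglik": loglik, "k": k, "aic": aic, "bic": bic})
    table = pd.DataFrame(rows).set_index("model")
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["rel_lik_aic"] = np.exp(-table["delta_aic"] / 2)
    table["akaike_weight"] = table["rel_lik_aic"] / table["rel_lik_aic"].sum()
    table["delta_bic"] = table["bic"] - table["bic"].min()
    table["rel_lik_bic"] = np.exp(-table["delta_bic"] / 2)
    return table.sort_values("aic")


def explore_fraction(
    states: StateSequence, bins: Optional[int] = None
) -> Union[float, np.ndarray]:
    """Proportion of trials labeled explore, overall or per equal-width
    within-session bin (e.g. bins=3 for early/mid/late)."""
    binary = states.binary_explore
    n = len(binary)
    if n == 0:
        raise ValueError("empty state sequence")
    if bins is None:
        return float(binary.mean())
    if bins > n:
        raise ValueError("more bins than trials")
    edges = np.linspace(0, n, bins + 1).astype(int)
    return np.array(
        [binary[edges[i] : edges[i + 1]].mean() for i in range(bins)]
    )


def simulate_tied_hmm(
    a: float,
    d: float,
    n_trials: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> tuple[np.ndarray, StateSequence]:
    """Generate choices (and true states) from the tied two-parameter
    model, starting in the explore state. State dynamics do not depend on
    rewards, so the choice sequence alone defines the process."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.empty(n_trials, dtype=np.int64)
    choices = np.empty(n_trials, dtype=np.int8)
    u_state = rng.random(n_trials)
    u_choice = rng.random(n_trials)
    half_leave = (1.0 - a) / 2.0
    z = STATE_EXPLORE
    for t in range(n_trials):
        states[t] = z
        if z == STATE_EXPLORE:
            choices[t] = 1 if u_choice[t] < 0.5 else 0
            u = u_state[t]
            z = 0 if u < a else (1 if u < a + half_leave else 2)
        else:
            choices[t] = 0 if z == STATE_EXPLOIT_L else 1
            if u_state[t] >= d:
                z = STATE_EXPLORE
    return choices, StateSequence(states)
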