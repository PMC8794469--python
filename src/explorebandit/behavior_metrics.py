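"""Model-free and cross-method behavioral statistics on labeled sessions.

All lagged statistics (win-stay/lose-shift, conditional mutual
information) align the outcome trial t-1 with the current choice at t and
exclude the first trial of each session; state-conditioned versions use
the latent label of trial t-1, the trial whose outcome is being learned
from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bandit_env import Session, chance_reward_rate
from .explore_hmm import StateSequence
from .rl_models import LatentTrace

__all__ = [
    "reward_vs_chance",
    "wsls_rates",
    "conditional_mutual_info",
    "cmi_from_joint",
    "tetrachoric_corr",
    "auc_separability",
    "latency_by_state",
    "explore_value_orthogonality",
    "matching_law_points",
]


def reward_vs_chance(session: Session) -> tuple[float, float]:
    """Obtained reward rate versus the rate a uniformly random chooser
    would earn on the same schedule."""
    if session.schedule is None:
        raise ValueError("session has no reward schedule attached")
    return float(session.rewards.mean()), chance_reward_rate(session.schedule)


def _stay_mask(choices: np.ndarray) -> np.ndarray:
    return (choices[1:] == choices[:-1]).astype(float)


def wsls_rates(
    session: Session, states: Optional[StateSequence] = None
) -> dict[str, Optional[float]]:
    """Win-stay and lose-shift rates, optionally split by the latent state
    of the outcome trial (t-1).

    Returns a dict with keys ``win_stay``, ``lose_shift`` and, when states
    are given, ``win_stay_explore``, ``win_stay_exploit``,
    ``lose_shift_explore``, ``lose_shift_exploit``. Conditions that never
    occur yield None rather than 0.
    """
    if session.n_trials < 2:
        raise ValueError("need at least two trials")
    stay = _stay_mask(session.choices)
    prev_reward = session.rewards[:-1]

    def rate(mask: np.ndarray, shift: bool) -> Optional[float]:
        if mask.sum() == 0:
            return None
        vals = 1.0 - stay[mask] if shift else stay[mask]
        return float(vals.mean())

    out: dict[str, Optional[float]] = {
        "win_stay": rate(prev_reward == 1, shift=False),
        "lose_shift": rate(prev_reward == 0, shift=True),
    }
    if states is not None:
        if len(states) != session.n_trials:
            raise ValueError("states misaligned with session")
        prev_explore = states.binary_explore[:-1] == 1
        out["win_stay_explore"] = rate((prev_reward == 1) & prev_explore, False)
        out["win_stay_exploit"] = rate((prev_reward == 1) & ~prev_explore, False)
        out["lose_shift_explore"] = rate((prev_reward == 0) & prev_explore, True)
        out["lose_shift_exploit"] = rate((prev_reward == 0) & ~prev_explore, True)
    return out


def cmi_from_joint(joint: np.ndarray) -> float:
    """Conditional mutual information I(C_t; C_{t-1} | R) in bits from a
    (possibly unnormalized) joint table indexed [c_t, c_prev, r].
    Zero-probability cells contribute zero."""
    p = np.asarray(joint, dtype=float)
    if p.shape != (2, 2, 2):
        raise ValueError("joint must be 2x2x2 (c_t, c_prev, r)")
    total = p.sum()
    if total <= 0:
        raise ValueError("joint table is empty")
    p = p / total
    p_r = p.sum(axis=(0, 1))
    p_ct_r = p.sum(axis=1)
    p_cp_r = p.sum(axis=0)
    cmi = 0.0
    for ct in range(2):
        for cp in range(2):
            for r in range(2):
                pj = p[ct, cp, r]
                if pj <= 0:
                    continue
                denom = p_ct_r[ct, r] * p_cp_r[cp, r]
                if denom <= 0:
                    continue
                cmi += pj * math.log2(p_r[r] * pj / denom)
    return max(cmi, 0.0)


def conditional_mutual_info(session: Session) -> float:
    """Plug-in estimate of I(C_t; C_{t-1} | R_{t-1}) in bits from the
    empirical joint distribution of a session."""
    if session.n_trials < 2:
        raise ValueError("need at least two trials")
    joint = np.zeros((2, 2, 2))
    np.add.at(
        joint,
        (session.choices[1:], session.choices[:-1], session.rewards[:-1]),
        1.0,
    )
    return cmi_from_joint(joint)


def tetrachoric_corr(
    labels_a: Sequence[int], labels_b: Sequence[int]
) -> float:
    """Maximum-likelihood tetrachoric correlation between two binary label
    sequences: the correlation of a latent bivariate normal whose
    dichotomization reproduces the 2x2 contingency table. Zero cells get a
    +0.5 continuity correction; a margin that is entirely one-valued has
    no defined correlation and raises."""
    a = np.asarray(labels_a).astype(int)
    b = np.asarray(labels_b).astype(int)
    if a.shape != b.shape:
        raise ValueError("label sets must have equal length")
    table = np.zeros((2, 2))
    np.add.at(table, (a, b), 1.0)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("a margin is entirely one-valued; r_tet undefined")
    if (table > 0).sum() < 4:
        table = table + 0.5
    n = table.sum()
    # dichotomization thresholds: label 1 <=> latent variable above h (k)
    h = stats.norm.isf(table[1, :].sum() / n)
    k = stats.norm.isf(table[:, 1].sum() / n)
    p11 = table[1, 1] / n

    def upper_orthant(rho: float) -> float:
        # P(X > h, Y > k) under the bivariate normal with correlation rho
        cdf = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True
        ).cdf([-h, -k])
        return float(cdf)

    def objective(rho: float) -> float:
        return upper_orthant(rho) - p11

    lo, hi = -0.9999, 0.9999
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo > 0:
        return -1.0
    if f_hi < 0:
        return 1.0
    return float(optimize.brentq(objective, lo, hi, xtol=1e-8))


def auc_separability(
    values_group_a: Sequence[float], values_group_b: Sequence[float]
) -> dict[str, float]:
    """Rank-based (Mann-Whitney) ROC AUC for separating two groups, with
    Hanley-McNeil standard error, a normal-approximation 95% CI, and the
    Mann-Whitney p-value. AUC is P(b > a) + 0.5 P(b = a); 1.0 means group
    B values are uniformly larger than group A's."""
    a = np.asarray(values_group_a, dtype=float)
    b = np.asarray(values_group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    pooled = np.concatenate([a, b])
    degenerate = np.allclose(pooled, pooled[0])
    if degenerate:
        return {
            "auc": 0.5,
            "se": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_value": 1.0,
            "degenerate": True,
        }
    res = stats.mannwhitneyu(b, a, alternative="two-sided")
    auc = float(res.statistic / (a.size * b.size))
    # Hanley & McNeil (1982) SE
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = math.sqrt(
        (auc * (1 - auc) + (a.size - 1) * (q1 - auc**2) + (b.size - 1) * (q2 - auc**2))
        / (a.size * b.size)
    )
    return {
        "auc": auc,
        "se": se,
        "ci_low": auc - 1.96 * se,
        "ci_high": auc + 1.96 * se,
        "p_value": float(res.pvalue),
        "degenerate": False,
    }


def _label_regression(rt: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Standardized coefficient and R^2 of z-scored RT on a binary label."""
    if np.std(labels) == 0 or np.std(rt) == 0:
        return 0.0, 0.0
    z_rt = (rt - rt.mean()) / rt.std()
    z_lab = (labels - labels.mean()) / labels.std()
    beta = float(np.mean(z_rt * z_lab))
    return beta, beta**2


def latency_by_state(
    session: Session,
    states_hmm: StateSequence,
    states_rl: Optional[np.ndarray] = None,
) -> dict[str, float]:
    """Mean response time per latent state and the variance in RT
    explained by each label set (standardized coefficient and R^2 from a
    simple regression of z-scored RT on the binary explore label)."""
    if session.response_time is None:
        raise ValueError("session has no response times")
    rt = np.asarray(session.response_time, dtype=float)
    explore = states_hmm.binary_explore.astype(float)
    out: dict[str, float] = {}
    for name, mask in (("rt_explore", explore == 1), ("rt_exploit", explore == 0)):
        out[name] = float(rt[mask].mean()) if mask.any() else np.nan
    coef, r2 = _label_regression(rt, explore)
    out["rt_coef_hmm"], out["rt_r2_hmm"] = coef, r2
    if states_rl is not None:
        coef, r2 = _label_regression(rt, np.asarray(states_rl, dtype=float))
        out["rt_coef_rl"], out["rt_r2_rl"] = coef, r2
    return out


def explore_value_orthogonality(
    sessions: Union[Session, Sequence[Session]],
    states: Union[StateSequence, Sequence[StateSequence]],
    trace: LatentTrace,
) -> float:
    """Mean relative value (Q_chosen - Q_unchosen) of explore-labeled
    choices; a value near zero means exploration is orthogonal to reward
    value. Raises if no trial is labeled explore."""
    if isinstance(sessions, Session):
        sessions = [sessions]
    if isinstance(states, StateSequence):
        states = [states]
    choices = np.concatenate([s.choices for s in sessions])
    explore = np.concatenate([st.binary_explore for st in states])
    if choices.shape[0] != trace.q.shape[0]:
        raise ValueError("trace misaligned with sessions")
    q_chosen = trace.q[np.arange(len(choices)), choices]
    q_unchosen = trace.q[np.arange(len(choices)), 1 - choices]
    mask = explore == 1
    if not mask.any():
        raise ValueError("no explore-labeled trials")
    return float((q_chosen - q_unchosen)[mask].mean())


def matching_law_points(
    sessions: Union[Session, Sequence[Session]],
) -> pd.DataFrame:
    """Per-session (reward fraction to arm 1, choice fraction to arm 1)
    pairs; a perfectly matching chooser lies on the diagonal."""
    if isinstance(sessions, Session):
        sessions = [sessions]
    rows = []
    for s in sessions:
        total_reward = s.rewards.sum()
        reward_frac = (
            float(s.rewards[s.choices == 1].sum() / total_reward)
            if total_reward > 0
            else np.nan
        )
        rows.append(
            {
                "subject_id": s.subject_id,
                "session_index": s.session_index,
                "reward_fraction_right": reward_frac,
                "choice_fraction_right": float((s.choices == 1).mean()),
            }
        )
    return pd.DataFrame(rows)
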