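"""Energy-landscape view of explore/exploit dynamics.

A fitted transition matrix defines a Markov chain whose stationary
distribution gives the long-run occupancy of each state. Treating the
chain as a physical system in equilibrium, state occupancies map to
energetic depths via the Boltzmann distribution
(E_j - E_i = ln(p_i / p_j) * k_B T), and escape rates map to barrier
heights via the Arrhenius equation (E_a = -ln(k / A) * k_B T with escape
rate k = 1 - stay probability). Both k_B T and the pre-exponential factor
A are fixed to 1, so energies are in natural-log units and only
differences are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .explore_hmm import HmmFit, build_transition_matrix

__all__ = [
    "NonErgodicError",
    "LandscapeSummary",
    "stationary_distribution",
    "state_energies",
    "activation_energy",
    "landscape_summary",
]


class NonErgodicError(ValueError):
    """The chain has no unique stationary distribution."""


@dataclass
class LandscapeSummary:
    """Group-level landscape: stationary occupancy of explore vs exploit,
    Boltzmann depth difference (E_exploit - E_explore), and Arrhenius
    barriers out of each state."""

    pi_explore: float
    pi_exploit: float
    depth_difference: float
    barrier_from_explore: float
    barrier_from_exploit: float
    group: Optional[str] = None
    n_subjects: int = 1
    pi_explore_sd: float = 0.0

    def profile(self) -> np.ndarray:
        """Three-point energy profile (explore floor, barrier peak,
        exploit floor) with the explore floor placed at zero; the
        absolute placement is a plotting convention."""
        return np.array(
            [0.0, self.barrier_from_explore, self.depth_difference]
        )


def stationary_distribution(
    transition_matrix: np.ndarray, collapse_exploit: bool = True
) -> np.ndarray:
    """Normalized left eigenvector of a row-stochastic matrix with
    eigenvalue 1.

    For the three-state explore/exploit chain the two exploit states are
    reported summed into a single "exploit" mass when
    ``collapse_exploit`` is true. Raises :class:`NonErgodicError` if the
    unit eigenvalue is not unique (reducible or periodic chain).
    """
    A = np.asarray(transition_matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("transition matrix must be square")
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows must sum to 1")
    eigvals, eigvecs = np.linalg.eig(A.T)
    close = np.isclose(eigvals, 1.0, atol=1e-8)
    if close.sum() != 1:
        raise NonErgodicError(
            f"{int(close.sum())} unit eigenvalues; chain is not ergodic"
        )
    # any other eigenvalue on the unit circle means periodicity
    others = np.abs(eigvals[~close])
    if others.size and np.any(others > 1.0 - 1e-10):
        raise NonErgodicError("unit-modulus eigenvalue; chain is periodic")
    pi = np.real(eigvecs[:, close.argmax()])
    pi = pi / pi.sum()
    if np.any(pi < -1e-10):
        raise NonErgodicError("negative stationary mass")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    if collapse_exploit and pi.shape[0] == 3:
        return np.array([pi[0], pi[1] + pi[2]])
    return pi


def state_energies(stationary: Sequence[float], kBT: float = 1.0) -> float:
    """Boltzmann depth difference E_exploit - E_explore =
    ln(p_explore / p_exploit) * kBT."""
    pi = np.asarray(stationary, dtype=float)
    if pi.shape[0] != 2:
        raise ValueError("expected a 2-state (explore, exploit) distribution")
    if np.any(pi <= 0):
        raise ValueError("stationary probabilities must be strictly positive")
    return float(np.log(pi[0] / pi[1]) * kBT)


def activation_energy(stay_prob: float, A: float = 1.0, kBT: float = 1.0) -> float:
    """Arrhenius barrier to escape a state with the given stay
    probability: escape rate k = 1 - stay, E_a = -ln(k / A) * kBT."""
    if not 0.0 <= stay_prob < 1.0:
        raise ValueError(
            "stay_prob must be in [0, 1); stay_prob = 1 is an infinite barrier"
        )
    return float(-np.log((1.0 - stay_prob) / A) * kBT)


def _tied_stay_probs(fit: HmmFit) -> tuple[float, float]:
    p = fit.spec.params
    if fit.spec.variant == "tied2":
        return p["a"], p["d"]
    if fit.spec.variant == "nt4":
        return 1.0 - p["q_L"] - p["q_R"], (p["d_L"] + p["d_R"]) / 2.0
    raise ValueError("landscape summaries are defined for reward-free variants")


def landscape_summary(
    fits_by_group: Mapping[str, Sequence[HmmFit]],
) -> dict[str, LandscapeSummary]:
    """Per-group landscape from per-subject fits.

    Stationary distributions are computed per subject and averaged within
    the group (the mean of stationary distributions, not the stationary
    distribution of mean parameters — the two differ); depths come from
    the group-mean occupancies and barriers from the group-mean stay
    probabilities. Subjects whose chains are non-ergodic are excluded.
    """
    out: dict[str, LandscapeSummary] = {}
    for group, fits in fits_by_group.items():
        if len(fits) == 0:
            raise ValueError(f"group {group!r} has no fits")
        pis, stays = [], []
        for fit in fits:
            try:
                pi = stationary_distribution(build_transition_matrix(fit.spec))
            except NonErgodicError:
                continue
            pis.append(pi)
            stays.append(_tied_stay_probs(fit))
        if not pis:
            raise NonErgodicError(f"no ergodic subjects in group {group!r}")
        pi_mean = np.mean(pis, axis=0)
        stay_mean = np.mean(stays, axis=0)
        out[group] = LandscapeSummary(
            pi_explore=float(pi_mean[0]),
            pi_exploit=float(pi_mean[1]),
            depth_difference=state_energies(pi_mean),
            barrier_from_explore=activation_energy(float(stay_mean[0])),
            barrier_from_exploit=activation_energy(float(stay_mean[1])),
            group=group,
            n_subjects=len(pis),
            pi_explore_sd=float(np.std([p[0] for p in pis], ddof=0)),
        )
    return out


def landscape_table(summaries: Mapping[str, LandscapeSummary]) -> pd.DataFrame:
    rows = [
        {
            "group": s.group,
            "n_subjects": s.n_subjects,
            "pi_explore": s.pi_explore,
            "pi_exploit": s.pi_exploit,
            "pi_explore_sd": s.pi_explore_sd,
            "depth_difference": s.depth_difference,
            "barrier_explore": s.barrier_from_explore,
            "barrier_exploit": s.barrier_from_exploit,
        }
        for s in summaries.values()
    ]
    return pd.DataFrame(rows).set_index("group")
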