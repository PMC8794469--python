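"""Inter-switch run lengths and geometric-mixture modeling.

If choice runs end probabilistically, run durations are geometrically
distributed; several switching regimes operating at different rates (a
fast-switching explore-like regime, a slow exploit-like one) yield a
mixture of geometrics on support {1, 2, ...}:
P(x | p) = (1 - p)^(x-1) p, with component mean 1/p.
Mixtures are fit by EM and compared by sequential likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeomMixFit",
    "run_lengths",
    "geometric_mixture_em",
    "simulate_geometric_mixture",
    "mixture_model_selection",
    "LOW_WEIGHT_THRESHOLD",
]

#: components below this weight are flagged as negligible in the selection
#: table (the discard heuristic used when counting meaningful regimes)
LOW_WEIGHT_THRESHOLD = 0.03


@dataclass
class GeomMixFit:
    """EM fit of a K-component geometric mixture, components sorted by
    mean (1/p) ascending."""

    n_components: int
    weights: np.ndarray
    success_probs: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list = None

    @property
    def means(self) -> np.ndarray:
        return 1.0 / self.success_probs


def run_lengths(choices: Sequence[int]) -> np.ndarray:
    """Lengths of maximal constant-choice runs, in order; the final
    (right-censored) run is included. Strict alternation gives all ones."""
    c = np.asarray(choices)
    if c.size < 1:
        raise ValueError("need at least one trial")
    boundaries = np.flatnonzero(np.diff(c) != 0)
    edges = np.concatenate([[-1], boundaries, [c.size - 1]])
    return np.diff(edges).astype(np.int64)


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=1, keepdims=True))).ravel()


def geometric_mixture_em(
    lengths: Sequence[int],
    n_components: int = 2,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: Optional[int] = None,
) -> GeomMixFit:
    """Fit a mixture of geometric distributions by EM, best of restarts.

    For one component the EM fixed point is the closed-form MLE
    p = 1/mean, reached after a single iteration.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size == 0:
        raise ValueError("empty run-length input")
    if np.any(x < 1):
        raise ValueError("run lengths must be >= 1")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    rng = np.random.default_rng(seed)
    best: Optional[GeomMixFit] = None
    for restart in range(n_restarts):
        if n_components == 1:
            w = np.ones(1)
            p = np.array([1.0 / x.mean()])
        else:
            w = rng.dirichlet(np.ones(n_components))
            p = rng.uniform(0.05, 1.0, size=n_components)
        prev_ll = -np.inf
        converged = False
        trace = []
        for it in range(1, max_iter + 1):
            logpmf = (x[:, None] - 1) * np.log1p(-np.clip(p, None, 1 - 1e-12)[None, :]) + np.log(
                np.clip(p, 1e-12, None)[None, :]
            )
            logjoint = logpmf + np.log(np.clip(w, 1e-300, None)[None, :])
            lognorm = _logsumexp_rows(logjoint)
            ll = float(lognorm.sum())
            trace.append(ll)
            resp = np.exp(logjoint - lognorm[:, None])
            if ll - prev_ll < tol and it > 1:
                converged = True
                break
            prev_ll = ll
            nk = resp.sum(axis=0)
            w = nk / x.size
            p = np.clip(nk / (resp * x[:, None]).sum(axis=0), 1e-9, 1.0)
        order = np.argsort(1.0 / p)
        fit = GeomMixFit(
            n_components=n_components,
            weights=w[order],
            success_probs=p[order],
            loglik=ll,
            n_iter=it,
            converged=converged,
            loglik_trace=trace,
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
        if n_components == 1:
            break
    return best


def simulate_geometric_mixture(
    n: int,
    weights: Sequence[float],
    means: Sequence[float],
    seed: Optional[int] = None,
) -> np.ndarray:
    """Draw run lengths from a mixture of geometrics given component means
    (1/p) and weights."""
    w = np.asarray(weights, dtype=float)
    p = 1.0 / np.asarray(means, dtype=float)
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(w), size=n, p=w / w.sum())
    return rng.geometric(p[comp]).astype(np.int64)


def mixture_model_selection(
    lengths: Sequence[int],
    max_components: int = 4,
    n_restarts: int = 10,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Fit K = 1..max_components mixtures and run sequential likelihood-
    ratio tests of K versus K-1 components (chi-square with df equal to
    the parameter difference; the usual mixture-boundary caveat applies).
    Components with weight below 3% are flagged as negligible."""
    if max_components < 2:
        raise ValueError("max_components must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    prev_fit: Optional[GeomMixFit] = None
    for k in range(1, max_components + 1):
        fit = geometric_mixture_em(
            lengths, k, n_restarts=n_restarts, seed=int(rng.integers(0, 2**31 - 1))
        )
        n_params = 2 * k - 1  # K success probs + (K-1) free weights
        if prev_fit is None:
            p_value = np.nan
        else:
            lr = 2.0 * (fit.loglik - prev_fit.loglik)
            p_value = float(stats.chi2.sf(max(lr, 0.0), df=2))
        rows.append(
            {
                "n_components": k,
                "loglik": fit.loglik,
                "n_params": n_params,
                "lrt_p_value": p_value,
                "weights": fit.weights.round(6).tolist(),
                "means": fit.means.round(4).tolist(),
                "negligible_components": int((fit.weights < LOW_WEIGHT_THRESHOLD).sum()),
            }
        )
        prev_fit = fit
    return pd.DataFrame(rows)
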