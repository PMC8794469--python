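"""Numba kernels for the sequential inner loops (HMM recursions, RL
likelihoods). All kernels operate on plain float64/int8 arrays; model
structure (emissions, parameter tying, resets) is decided by the callers."""

from __future__ import annotations

import numpy as np
from numba import njit

# RL model codes shared with rl_models
M_RANDOM = 0
M_WSLS = 1
M_RL = 2
M_RL_EPS = 3
M_RLCK = 4
M_RLCK_GAMMA = 5
M_RLCK_ETA = 6

_TINY = 1e-300


@njit(cache=True)
def hmm_forward(emis, trans_stack, step_class):
    """Scaled forward pass. emis: (T, S); trans_stack: (C, S, S) row-
    stochastic matrices; step_class[t-1] selects the matrix governing the
    transition into trial t. Initial state is state 0 with probability 1.
    Returns (loglik, alpha) with alpha row-normalized."""
    T, S = emis.shape
    alpha = np.zeros((T, S))
    loglik = 0.0
    for j in range(S):
        alpha[0, j] = 0.0
    alpha[0, 0] = emis[0, 0]
    norm = alpha[0, :].sum()
    if norm < _TINY:
        norm = _TINY
    alpha[0, :] /= norm
    loglik += np.log(norm)
    for t in range(1, T):
        A = trans_stack[step_class[t - 1]]
        norm = 0.0
        for j in range(S):
            s = 0.0
            for i in range(S):
                s += alpha[t - 1, i] * A[i, j]
            s *= emis[t, j]
            alpha[t, j] = s
            norm += s
        if norm < _TINY:
            norm = _TINY
        for j in range(S):
            alpha[t, j] /= norm
        loglik += np.log(norm)
    return loglik, alpha


@njit(cache=True)
def hmm_forward_backward(emis, trans_stack, step_class):
    """Forward-backward with expected transition counts pooled per
    transition-matrix class. Returns (loglik, xi) where
    xi[c, i, j] = sum over steps of class c of P(z_t=i, z_{t+1}=j | data)."""
    T, S = emis.shape
    C = trans_stack.shape[0]
    loglik, alpha = hmm_forward(emis, trans_stack, step_class)
    beta = np.empty(S)
    beta_next = np.empty(S)
    for j in range(S):
        beta[j] = 1.0
    xi = np.zeros((C, S, S))
    for t in range(T - 2, -1, -1):
        c = step_class[t]
        A = trans_stack[c]
        # unnormalized xi for the step t -> t+1
        denom = 0.0
        for i in range(S):
            for j in range(S):
                denom += alpha[t, i] * A[i, j] * emis[t + 1, j] * beta[j]
        if denom < _TINY:
            denom = _TINY
        for i in range(S):
            for j in range(S):
                xi[c, i, j] += alpha[t, i] * A[i, j] * emis[t + 1, j] * beta[j] / denom
        # backward recursion (scaled)
        norm = 0.0
        for i in range(S):
            s = 0.0
            for j in range(S):
                s += A[i, j] * emis[t + 1, j] * beta[j]
            beta_next[i] = s
            norm += s
        if norm < _TINY:
            norm = _TINY
        for i in range(S):
            beta[i] = beta_next[i] / norm
    return loglik, xi


@njit(cache=True)
def hmm_viterbi(emis, trans_stack, step_class):
    """Most probable state path (log-space). Trial 1 is constrained to
    state 0; ties break toward the lowest state index."""
    T, S = emis.shape
    NEG = -1e30
    logv = np.full((T, S), NEG)
    back = np.zeros((T, S), dtype=np.int64)
    if emis[0, 0] > 0.0:
        logv[0, 0] = np.log(emis[0, 0])
    for t in range(1, T):
        A = trans_stack[step_class[t - 1]]
        for j in range(S):
            if emis[t, j] <= 0.0:
                continue
            best = NEG
            arg = 0
            for i in range(S):
                if logv[t - 1, i] <= NEG or A[i, j] <= 0.0:
                    continue
                v = logv[t - 1, i] + np.log(A[i, j])
                if v > best:
                    best = v
                    arg = i
            if best > NEG:
                logv[t, j] = best + np.log(emis[t, j])
                back[t, j] = arg
    path = np.zeros(T, dtype=np.int64)
    best = NEG
    for j in range(S):
        if logv[T - 1, j] > best:
            best = logv[T - 1, j]
            path[T - 1] = j
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


@njit(cache=True)
def rl_trial_probs(model, params, choices, rewards, session_starts):
    """Per-trial P(choose right) plus latent value/kernel traces.

    params layout: [b, eps, alpha, beta, alpha_c, beta_c, gamma, eta]
    (unused slots ignored per model). Q and CK reset at session starts.
    Returns (p_right (T,), Q (T, 2), CK (T, 2)) where Q[t], CK[t] are the
    values *used* on trial t (pre-update).
    """
    T = choices.shape[0]
    b = params[0]
    eps = params[1]
    alpha = params[2]
    beta = params[3]
    alpha_c = params[4]
    beta_c = params[5]
    gamma = params[6]
    eta = params[7]
    p_right = np.empty(T)
    Q = np.empty((T, 2))
    CK = np.empty((T, 2))
    q0 = 0.5
    q1 = 0.5
    ck0 = 0.0
    ck1 = 0.0
    start_idx = 0
    n_starts = session_starts.shape[0]
    for t in range(T):
        if start_idx < n_starts and session_starts[start_idx] == t:
            q0 = 0.5
            q1 = 0.5
            ck0 = 0.0
            ck1 = 0.0
            start_idx += 1
            first = True
        else:
            first = False
        Q[t, 0] = q0
        Q[t, 1] = q1
        CK[t, 0] = ck0
        CK[t, 1] = ck1
        if model == M_RANDOM:
            p1 = 1.0 - b
        elif model == M_WSLS:
            if first:
                p1 = 0.5
            else:
                prev_c = choices[t - 1]
                prev_r = rewards[t - 1]
                if prev_r == 1:
                    p_stay = 1.0 - eps / 2.0
                else:
                    p_stay = eps / 2.0
                p1 = p_stay if prev_c == 1 else 1.0 - p_stay
        else:
            if model == M_RL or model == M_RL_EPS:
                logit = beta * (q1 - q0)
            elif model == M_RLCK or model == M_RLCK_GAMMA:
                logit = beta * (q1 - q0) + beta_c * (ck1 - ck0)
            else:  # M_RLCK_ETA
                logit = eta * beta * (q1 - q0) + (1.0 - eta) * beta_c * (ck1 - ck0)
            if logit > 35.0:
                p1 = 1.0
            elif logit < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-logit))
            if model == M_RL_EPS:
                p1 = eps + (1.0 - 2.0 * eps) * p1
        p_right[t] = p1
        # updates for the next trial
        c = choices[t]
        r = rewards[t]
        if model >= M_RL:
            lr = alpha
            if model == M_RLCK_GAMMA and r == 0:
                lr = gamma * alpha
            if c == 0:
                q0 = q0 + lr * (r - q0)
            else:
                q1 = q1 + lr * (r - q1)
        if model >= M_RLCK:
            if c == 0:
                ck0 = ck0 + alpha_c * (1.0 - ck0)
                ck1 = ck1 + alpha_c * (0.0 - ck1)
            else:
                ck0 = ck0 + alpha_c * (0.0 - ck0)
                ck1 = ck1 + alpha_c * (1.0 - ck1)
    return p_right, Q, CK


@njit(cache=True)
def nll_from_probs(p_right, choices):
    nll = 0.0
    T = choices.shape[0]
    for t in range(T):
        p = p_right[t] if choices[t] == 1 else 1.0 - p_right[t]
        if p < 1e-12:
            p = 1e-12
        nll -= np.log(p)
    return nll
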