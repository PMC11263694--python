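"""Scaled forward-backward and Viterbi kernels.

Compiled with numba when available; the pure-Python fallback is identical
code and is only exercised if numba cannot be imported.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - import guard
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def em_step(obs, pi, A, B):
    """One Baum-Welch E-step with Rabiner scaling.

    Returns the log-likelihood of the current parameters together with the
    unnormalized sufficient statistics (gamma at t=0, transition counts,
    emission counts); the M-step normalization happens in the caller.
    """
    T = obs.shape[0]
    S = A.shape[0]
    M = B.shape[1]

    alpha = np.empty((T, S))
    c = np.empty(T)
    for i in range(S):
        alpha[0, i] = pi[i] * B[i, obs[0]]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = acc * B[j, obs[t]]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]

    beta = np.ones(S)
    A_num = np.zeros((S, S))
    B_num = np.zeros((S, M))
    g = alpha[T - 1] * beta
    g /= g.sum()
    for i in range(S):
        B_num[i, obs[T - 1]] += g[i]
    gamma0 = g.copy()
    for t in range(T - 2, -1, -1):
        beta_new = np.empty(S)
        for i in range(S):
            acc = 0.0
            for j in range(S):
                tmp = A[i, j] * B[j, obs[t + 1]] * beta[j]
                A_num[i, j] += alpha[t, i] * tmp / c[t + 1]
                acc += tmp
            beta_new[i] = acc / c[t + 1]
        beta = beta_new
        g = alpha[t] * beta
        g /= g.sum()
        for i in range(S):
            B_num[i, obs[t]] += g[i]
        if t == 0:
            gamma0 = g.copy()

    loglik = np.log(c).sum()
    return loglik, gamma0, A_num, B_num


@njit(cache=True)
def viterbi_path(obs, log_pi, log_A, log_B):
    """Most probable path in log space; ties break toward the lower index."""
    T = obs.shape[0]
    S = log_A.shape[0]
    delta = np.empty((T, S))
    psi = np.zeros((T, S), dtype=np.int64)
    for i in range(S):
        delta[0, i] = log_pi[i] + log_B[i, obs[0]]
    for t in range(1, T):
        for j in range(S):
            best = -np.inf
            arg = 0
            for i in range(S):
                v = delta[t - 1, i] + log_A[i, j]
                if v > best:  # strict: first (lowest) index wins on ties
                    best = v
                    arg = i
            delta[t, j] = best + log_B[j, obs[t]]
            psi[t, j] = arg
    best = -np.inf
    arg = 0
    for i in range(S):
        if delta[T - 1, i] > best:
            best = delta[T - 1, i]
            arg = i
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
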