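"""Compiled inner loops for the sequential-attention model likelihood.

The per-trial recursion cannot be vectorized across trials (the attention
state is sequential), so the trace is compiled with numba. Inputs are the
per-trial match vector of the *chosen* pile and the feedback flag; the
chosen-pile choice probability only needs that match vector because each
dimension of a card matches exactly one pile.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["loglik_trace", "deviance_over_samples"]


@njit(cache=True)
def loglik_trace(
    m: np.ndarray,  # (T, 3) float64, match vector of chosen pile
    fb: np.ndarray,  # (T,) int64, 1 = right, 0 = wrong
    r: float,
    p: float,
    d: float,
    f: float,
    eps_c: float,
    eps_a: float,
) -> float:
    a0 = 1.0 / 3.0
    a1 = 1.0 / 3.0
    a2 = 1.0 / 3.0
    ll = 0.0
    for t in range(m.shape[0]):
        q0 = a0 ** d
        q1 = a1 ** d
        q2 = a2 ** d
        praw = (m[t, 0] * q0 + m[t, 1] * q1 + m[t, 2] * q2) / (q0 + q1 + q2)
        ll += np.log((1.0 - eps_c) * praw + eps_c * 0.25)
        g0 = a0 ** f
        g1 = a1 ** f
        g2 = a2 ** f
        if fb[t] == 1:
            w0 = m[t, 0] * g0
            w1 = m[t, 1] * g1
            w2 = m[t, 2] * g2
            rate = r
        else:
            w0 = (1.0 - m[t, 0]) * g0
            w1 = (1.0 - m[t, 1]) * g1
            w2 = (1.0 - m[t, 2]) * g2
            rate = p
        ws = w0 + w1 + w2
        if ws > 0.0:
            a0 = (1.0 - rate) * a0 + rate * w0 / ws
            a1 = (1.0 - rate) * a1 + rate * w1 / ws
            a2 = (1.0 - rate) * a2 + rate * w2 / ws
        if a0 < eps_a:
            a0 = eps_a
        if a1 < eps_a:
            a1 = eps_a
        if a2 < eps_a:
            a2 = eps_a
        s = a0 + a1 + a2
        a0 /= s
        a1 /= s
        a2 /= s
    return ll


@njit(cache=True)
def deviance_over_samples(
    m: np.ndarray,
    fb: np.ndarray,
    params: np.ndarray,  # (n, 4) columns r, p, d, f
    eps_c: float,
    eps_a: float,
) -> np.ndarray:
    out = np.empty(params.shape[0])
    for i in range(params.shape[0]):
        out[i] = -2.0 * loglik_trace(
            m, fb, params[i, 0], params[i, 1], params[i, 2], params[i, 3], eps_c, eps_a
        )
    return out
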