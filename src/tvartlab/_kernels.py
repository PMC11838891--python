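"""Numba kernels for the stochastic Heun integrator.

The integrator spends ~1e6 tiny vector steps per simulated two-minute
trajectory, so the inner loops are compiled.  Noise increments are
generated outside the kernels (NumPy Generator, seeded) and passed in as
chunks to keep memory bounded for long high-dimensional runs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SERIES_CUTOFF = 1e-8


@njit(cache=True, inline="always")
def _rate(u: float, d: float) -> float:
    z = d * u
    if abs(z) < _SERIES_CUTOFF:
        return 1.0 / d + u / 2.0
    return u / (-np.expm1(-z))


@njit(cache=True)
def _drift(S, K, I0, tau_s, gamma, a, b, d, out):
    N = S.shape[0]
    for i in range(N):
        x = I0
        for j in range(N):
            x += K[i, j] * S[j]
        R = _rate(a * x - b, d)
        out[i] = -S[i] / tau_s + gamma * (1.0 - S[i]) * R


@njit(cache=True)
def heun_chunk(S, K, I0, tau_s, gamma, a, b, d, dW, dt, stride, phase, out, n_written):
    """Advance the state through one chunk of noise increments.

    ``dW`` is (n_steps, N) of sigma-scaled Wiener increments.  A sample is
    recorded into ``out`` (before stepping) whenever the global step phase
    hits a multiple of ``stride`` and room remains; returns
    (new_phase, new_n_written, bad_step) with bad_step >= 0 flagging
    divergence (|S| > 10) at that step of the chunk.
    """
    N = S.shape[0]
    f0 = np.empty(N)
    f1 = np.empty(N)
    Sp = np.empty(N)
    n_steps = dW.shape[0]
    for step in range(n_steps):
        if phase == 0 and n_written < out.shape[0]:
            for i in range(N):
                out[n_written, i] = S[i]
            n_written += 1
        phase += 1
        if phase == stride:
            phase = 0
        _drift(S, K, I0, tau_s, gamma, a, b, d, f0)
        for i in range(N):
            Sp[i] = S[i] + f0[i] * dt + dW[step, i]
        _drift(Sp, K, I0, tau_s, gamma, a, b, d, f1)
        for i in range(N):
            S[i] = S[i] + 0.5 * (f0[i] + f1[i]) * dt + dW[step, i]
            if abs(S[i]) > 10.0:
                return phase, n_written, step
    return phase, n_written, -1


@njit(cache=True)
def heun_linear_chunk(S, A, dW, dt, stride, phase, out, n_written):
    """Same stepping scheme for the linear test field dS/dt = A@S."""
    N = S.shape[0]
    n_steps = dW.shape[0]
    f0 = np.empty(N)
    f1 = np.empty(N)
    Sp = np.empty(N)
    for step in range(n_steps):
        if phase == 0 and n_written < out.shape[0]:
            for i in range(N):
                out[n_written, i] = S[i]
            n_written += 1
        phase += 1
        if phase == stride:
            phase = 0
        for i in range(N):
            acc = 0.0
            for j in range(N):
                acc += A[i, j] * S[j]
            f0[i] = acc
        for i in range(N):
            Sp[i] = S[i] + f0[i] * dt + dW[step, i]
        for i in range(N):
            acc = 0.0
            for j in range(N):
                acc += A[i, j] * Sp[j]
            f1[i] = acc
        for i in range(N):
            S[i] = S[i] + 0.5 * (f0[i] + f1[i]) * dt + dW[step, i]
            if abs(S[i]) > 1e6:
                return phase, n_written, step
    return phase, n_written, -1


@njit(cache=True)
def integrate_to_equilibrium(S, K, I0, tau_s, gamma, a, b, d, dt, tol, max_steps, check_every):
    """Noiseless Heun integration until max|dS/dt| < tol.

    Returns (converged, steps_taken); S is updated in place.
    """
    N = S.shape[0]
    f0 = np.empty(N)
    f1 = np.empty(N)
    Sp = np.empty(N)
    for step in range(max_steps):
        _drift(S, K, I0, tau_s, gamma, a, b, d, f0)
        if step % check_every == 0:
            m = 0.0
            for i in range(N):
                if abs(f0[i]) > m:
                    m = abs(f0[i])
            if m < tol:
                return True, step
        for i in range(N):
            Sp[i] = S[i] + f0[i] * dt
        _drift(Sp, K, I0, tau_s, gamma, a, b, d, f1)
        for i in range(N):
            S[i] = S[i] + 0.5 * (f0[i] + f1[i]) * dt
    _drift(S, K, I0, tau_s, gamma, a, b, d, f0)
    m = 0.0
    for i in range(N):
        if abs(f0[i]) > m:
            m = abs(f0[i])
    return m < tol, max_steps
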