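"""Compiled integration kernels (numba).

All kernels take the graph as CSR-style neighbor lists (indptr, indices) and
use fixed-step arithmetic so that a given seed and configuration reproduces
bit-identical trajectories.  The Rössler kernel detects strict local minima
of y online, since storing every integration step of a long run would be
wasteful.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _kuramoto_rhs(theta, omega, indptr, indices, d, out):
    n = theta.shape[0]
    for i in range(n):
        acc = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            acc += np.sin(theta[indices[p]] - theta[i])
        out[i] = omega[i] + d * acc


@njit(cache=True)
def kuramoto_rk4(
    theta0, omega, indptr, indices, d, dt, n_transient_steps, n_samples, sample_every
):
    """Integrate the Kuramoto network; record phase and instantaneous
    frequency (the RHS, not a finite difference) every ``sample_every`` steps.

    Returns (theta_samples, freq_samples, theta_final)."""
    n = theta0.shape[0]
    theta = theta0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    theta_s = np.empty((n_samples, n))
    freq_s = np.empty((n_samples, n))
    total = n_transient_steps + n_samples * sample_every
    rec = 0
    for step in range(total):
        _kuramoto_rhs(theta, omega, indptr, indices, d, k1)
        for i in range(n):
            tmp[i] = theta[i] + 0.5 * dt * k1[i]
        _kuramoto_rhs(tmp, omega, indptr, indices, d, k2)
        for i in range(n):
            tmp[i] = theta[i] + 0.5 * dt * k2[i]
        _kuramoto_rhs(tmp, omega, indptr, indices, d, k3)
        for i in range(n):
            tmp[i] = theta[i] + dt * k3[i]
        _kuramoto_rhs(tmp, omega, indptr, indices, d, k4)
        for i in range(n):
            theta[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        done = step + 1 - n_transient_steps
        if done > 0 and done % sample_every == 0:
            _kuramoto_rhs(theta, omega, indptr, indices, d, k1)
            for i in range(n):
                theta_s[rec, i] = theta[i]
                freq_s[rec, i] = k1[i]
            rec += 1
    return theta_s, freq_s, theta


@njit(cache=True)
def chialvo_iterate(x0, y0, I, indptr, indices, d, a, b, c, n_transient, n_iter):
    """Iterate the coupled Chialvo map; return post-transient (x, y) series
    of shape (n_iter, N) plus the final state."""
    n = x0.shape[0]
    x = x0.copy()
    y = y0.copy()
    xn = np.empty(n)
    yn = np.empty(n)
    xs = np.empty((n_iter, n))
    ys = np.empty((n_iter, n))
    for t in range(n_transient + n_iter):
        for i in range(n):
            acc = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                acc += x[indices[p]] - x[i]
            xn[i] = x[i] * x[i] * np.exp(y[i] - x[i]) + I[i] + d * acc
            yn[i] = a * y[i] - b * x[i] + c
        for i in range(n):
            x[i] = xn[i]
            y[i] = yn[i]
            if np.abs(x[i]) > 1e6:
                raise ValueError("Chialvo map diverged (|x| > 1e6)")
        if t >= n_transient:
            for i in range(n):
                xs[t - n_transient, i] = x[i]
                ys[t - n_transient, i] = y[i]
    return xs, ys, x, y


@njit(cache=True)
def _rossler_rhs(state, w, indptr, indices, d, a, b, c, out):
    n = state.shape[0]
    for i in range(n):
        xi = state[i, 0]
        yi = state[i, 1]
        zi = state[i, 2]
        acc = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            acc += state[indices[p], 1] - yi
        out[i, 0] = -w[i] * yi - zi
        out[i, 1] = w[i] * xi + a * yi + d * acc
        out[i, 2] = b + zi * (xi - c)


@njit(cache=True)
def rossler_rk4(
    state0,
    w,
    indptr,
    indices,
    d,
    dt,
    n_transient_steps,
    n_steps,
    sample_every,
    a,
    b,
    c,
    max_extrema,
):
    """Integrate the y-coupled Rössler network.

    Post-transient, records (x, y) every ``sample_every`` steps for phase
    reconstruction and detects strict local minima of each node's y series
    online (three-point comparison on the integration grid).

    Returns (xy_samples[n_samples, N, 2], minima[N, max_extrema],
    minima_counts[N], final_state)."""
    n = state0.shape[0]
    state = state0.copy()
    k1 = np.empty((n, 3))
    k2 = np.empty((n, 3))
    k3 = np.empty((n, 3))
    k4 = np.empty((n, 3))
    tmp = np.empty((n, 3))
    n_samples = n_steps // sample_every
    xy = np.empty((n_samples, n, 2))
    minima = np.empty((n, max_extrema))
    counts = np.zeros(n, dtype=np.int64)
    prev1 = np.empty(n)  # y at step-1
    prev2 = np.empty(n)  # y at step-2
    rec = 0
    for step in range(n_transient_steps + n_steps):
        _rossler_rhs(state, w, indptr, indices, d, a, b, c, k1)
        for i in range(n):
            for q in range(3):
                tmp[i, q] = state[i, q] + 0.5 * dt * k1[i, q]
        _rossler_rhs(tmp, w, indptr, indices, d, a, b, c, k2)
        for i in range(n):
            for q in range(3):
                tmp[i, q] = state[i, q] + 0.5 * dt * k2[i, q]
        _rossler_rhs(tmp, w, indptr, indices, d, a, b, c, k3)
        for i in range(n):
            for q in range(3):
                tmp[i, q] = state[i, q] + dt * k3[i, q]
        _rossler_rhs(tmp, w, indptr, indices, d, a, b, c, k4)
        for i in range(n):
            for q in range(3):
                state[i, q] += (
                    dt
                    / 6.0
                    * (k1[i, q] + 2.0 * k2[i, q] + 2.0 * k3[i, q] + k4[i, q])
                )
            if not np.isfinite(state[i, 0]):
                raise ValueError("Rössler integration produced non-finite state")
        done = step + 1 - n_transient_steps
        if done >= 1:
            if done >= 3:
                for i in range(n):
                    yi = state[i, 1]
                    if prev1[i] < prev2[i] and prev1[i] < yi:
                        if counts[i] < max_extrema:
                            minima[i, counts[i]] = prev1[i]
                            counts[i] += 1
            for i in range(n):
                prev2[i] = prev1[i]
                prev1[i] = state[i, 1]
            if done % sample_every == 0:
                for i in range(n):
                    xy[rec, i, 0] = state[i, 0]
                    xy[rec, i, 1] = state[i, 1]
                rec += 1
    return xy, minima, counts, state
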