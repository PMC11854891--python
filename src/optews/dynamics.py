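"""Coupled dynamical systems: Kuramoto phases, Chialvo neural maps, and
y-coupled Rössler oscillators, plus the per-family phase definitions.

All three families share the diffusive-network form: each node runs its own
local dynamics (with a degree-correlated intrinsic parameter) and is driven
by the sum, over neighbors, of an output function of the state difference.
The coupling strength ``d`` is the normalized strength (sigma / k_max in the
usual convention), applied directly as the prefactor of the neighbor sum.

Observables feeding the ordinal analysis differ by family:

- Kuramoto: the instantaneous frequency ``dtheta_i/dt`` (the RHS evaluated at
  the sample instants), recorded every ``sample_every`` integration steps.
- Chialvo: the sequence of spike maxima of the membrane potential ``x``
  (strict local maxima above a threshold, default 0.5).
- Rössler: the sequence of strict local minima of ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .networks import NetworkSpec
from .ordinal import poincare_section

__all__ = [
    "CHIALVO_PARAMS",
    "ROSSLER_PARAMS",
    "SimulationRun",
    "simulate_kuramoto",
    "simulate_chialvo",
    "simulate_rossler",
    "chialvo_phase",
    "rossler_phase",
]

# Map/flow constants for the periodic-spiking and phase-coherent chaotic
# regimes, respectively.
CHIALVO_PARAMS = {"a": 0.89, "b": 0.6, "c": 0.28}
ROSSLER_PARAMS = {"a": 0.165, "b": 0.4, "c": 8.5}


@dataclass
class SimulationRun:
    """Retained trajectory of one network simulation at fixed coupling."""

    family: str
    coupling: float
    observables: np.ndarray | list  # per-node entropy input (see module doc)
    phases: np.ndarray | None  # (T, N) phase samples, or None (derive later)
    final_state: tuple  # carried into the next sweep point
    meta: dict = field(default_factory=dict)


def simulate_kuramoto(
    net: NetworkSpec,
    omega: np.ndarray,
    d: float,
    n_samples: int = 2000,
    dt: float = 0.01,
    sample_every: int = 200,
    transient: float = 200.0,
    theta0: np.ndarray | None = None,
    seed: int | None = None,
) -> SimulationRun:
    """RK4 integration of ``dtheta_i/dt = omega_i + d sum_j a_ij sin(theta_j
    - theta_i)``.

    ``transient`` is in time units and is discarded before recording
    ``n_samples`` phase/frequency samples spaced ``sample_every`` steps.
    ``theta0`` carries state along a sweep; otherwise phases start uniform
    at random from ``seed``.
    """
    if theta0 is None:
        theta0 = np.random.default_rng(seed).uniform(
            0.0, 2 * np.pi, size=net.n_nodes
        )
    theta0 = np.asarray(theta0, dtype=float)
    indptr, indices = net.edge_arrays()
    n_trans = int(round(transient / dt))
    theta_s, freq_s, theta_f = _kernels.kuramoto_rk4(
        theta0, np.asarray(omega, float), indptr, indices, float(d), dt,
        n_trans, n_samples, sample_every,
    )
    if not np.all(np.isfinite(theta_s)):
        raise FloatingPointError(
            f"Kuramoto integration produced non-finite phases at dt={dt}"
        )
    return SimulationRun(
        family="kuramoto",
        coupling=d,
        observables=freq_s,  # (T, N) instantaneous frequencies
        phases=theta_s,
        final_state=(theta_f,),
        meta={"dt": dt, "sample_every": sample_every, "transient": transient,
              "n_samples": n_samples, "seed": seed},
    )


def simulate_chialvo(
    net: NetworkSpec,
    currents: np.ndarray,
    d: float,
    n_iter: int = 60000,
    transient: int = 5000,
    state0: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int | None = None,
    params: dict | None = None,
) -> SimulationRun:
    """Exact iteration of the diffusively x-coupled Chialvo map.

    ``x`` acts as a membrane potential (spikes are its maxima above ~0.5) and
    ``y`` as a recovery variable; the bias current ``currents[i]`` sets each
    neuron's firing rate.
    """
    p = dict(CHIALVO_PARAMS, **(params or {}))
    if state0 is None:
        rng = np.random.default_rng(seed)
        x0 = rng.uniform(0.3, 1.2, size=net.n_nodes)
        y0 = rng.uniform(1.0, 2.0, size=net.n_nodes)
    else:
        x0, y0 = (np.asarray(v, dtype=float) for v in state0)
    indptr, indices = net.edge_arrays()
    xs, ys, xf, yf = _kernels.chialvo_iterate(
        x0, y0, np.asarray(currents, float), indptr, indices, float(d),
        p["a"], p["b"], p["c"], int(transient), int(n_iter),
    )
    return SimulationRun(
        family="chialvo",
        coupling=d,
        observables=xs,  # (T, N) membrane potential
        phases=None,  # built downstream from spike times
        final_state=(xf, yf),
        meta={"transient": transient, "n_iter": n_iter, "seed": seed, **p},
    )


def simulate_rossler(
    net: NetworkSpec,
    w: np.ndarray,
    d: float,
    t_total: float = 2000.0,
    dt: float = 0.01,
    transient: float = 200.0,
    sample_every: int = 20,
    state0: np.ndarray | None = None,
    seed: int | None = None,
    params: dict | None = None,
) -> SimulationRun:
    """RK4 integration of Rössler oscillators diffusively coupled in y.

    Records (x, y) every ``sample_every`` steps for phase reconstruction and
    collects each node's y-minima online (the Poincaré section used for the
    ordinal analysis).  ``observables`` is a list of per-node minima arrays
    (nodes generally spike at slightly different rates).
    """
    p = dict(ROSSLER_PARAMS, **(params or {}))
    if state0 is None:
        rng = np.random.default_rng(seed)
        state0 = np.column_stack([
            rng.uniform(-5, 5, size=net.n_nodes),
            rng.uniform(-5, 5, size=net.n_nodes),
            rng.uniform(0.0, 0.5, size=net.n_nodes),
        ])
    state0 = np.asarray(state0, dtype=float)
    indptr, indices = net.edge_arrays()
    n_trans = int(round(transient / dt))
    n_steps = int(round(t_total / dt))
    # phase-coherent Rössler completes a cycle in ~2*pi/w time units
    max_extrema = int(t_total / (2 * np.pi / 1.2) * 2) + 16
    xy, minima, counts, final = _kernels.rossler_rk4(
        state0, np.asarray(w, float), indptr, indices, float(d), dt,
        n_trans, n_steps, int(sample_every), p["a"], p["b"], p["c"],
        max_extrema,
    )
    obs = [minima[i, : counts[i]].copy() for i in range(net.n_nodes)]
    return SimulationRun(
        family="rossler",
        coupling=d,
        observables=obs,  # list of per-node y-minima sequences
        phases=np.unwrap(np.arctan2(xy[:, :, 1], xy[:, :, 0]), axis=0),
        final_state=(final,),
        meta={"dt": dt, "transient": transient, "t_total": t_total,
              "sample_every": sample_every, "seed": seed,
              "y_samples": xy[:, :, 1], **p},
    )


def chialvo_phase(
    x_series: np.ndarray,
    spike_threshold: float = 0.5,
    dt: float = 1.0,
) -> np.ndarray:
    """Spike-interpolated phase of a single neuron's membrane-potential
    series.

    The phase advances by 2*pi at each spike (strict local maximum above
    ``spike_threshold``) and is linear in time between consecutive spikes.
    Samples before the first or after the last spike have no defined phase
    and are returned as NaN.
    """
    sec = poincare_section(x_series, kind="maxima", threshold=spike_threshold)
    if len(sec) < 2:
        raise ValueError("need at least 2 spikes to define a phase")
    t = np.arange(len(x_series)) * dt
    spike_t = sec.indices * dt
    n = np.searchsorted(spike_t, t, side="right") - 1
    phase = np.full(len(x_series), np.nan)
    valid = (n >= 0) & (n < len(spike_t) - 1)
    nv = n[valid]
    phase[valid] = 2 * np.pi * nv + 2 * np.pi * (
        t[valid] - spike_t[nv]
    ) / (spike_t[nv + 1] - spike_t[nv])
    phase[sec.indices[-1]] = 2 * np.pi * (len(spike_t) - 1)
    return phase


def rossler_phase(x_series: np.ndarray, y_series: np.ndarray) -> np.ndarray:
    """Geometric phase arctan(y/x), quadrant-aware and unwrapped.

    Valid for the phase-coherent regime where the (x, y) projection circles
    the origin.  A sample at the origin carries the previous angle forward.
    """
    x = np.asarray(x_series, float)
    y = np.asarray(y_series, float)
    if x.shape != y.shape:
        raise ValueError("x and y series must have the same length")
    theta = np.arctan2(y, x)
    degenerate = (x == 0) & (y == 0)
    if degenerate.any():
        for i in np.nonzero(degenerate)[0]:
            theta[i] = theta[i - 1] if i > 0 else 0.0
    return np.unwrap(theta)
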