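"""Adiabatic coupling sweeps: order parameter, continuation, and critical
couplings.

A forward sweep increases the coupling ``d`` over a grid, starting from
random initial conditions and carrying the final state of each point into
the next one; a backward sweep starts from a synchronized state at the
largest coupling and descends.  At each grid point the per-node entropy
input (family-specific, see :mod:`optews.dynamics`), the normalized
permutation entropy H, the transition entropy HT, the fluctuation standard
deviation and the lag-1 autocorrelation are recorded together with the
time-averaged phase order parameter R.  Explosive transitions show up as a
single-step jump of R, and the forward/backward pair delimits the
hysteresis window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .dynamics import (
    SimulationRun,
    chialvo_phase,
    simulate_chialvo,
    simulate_kuramoto,
    simulate_rossler,
)
from .ews import autocorrelation_lag, fluctuation_std
from .networks import NetworkSpec
from .ordinal import opt_entropy_of_series, poincare_section

__all__ = [
    "SweepResult",
    "CriticalPoint",
    "order_parameter",
    "run_sweep",
    "critical_coupling",
    "hysteresis_width",
    "average_sweeps",
]


@dataclass
class SweepResult:
    """Per-coupling observables along one continuation (one realization)."""

    direction: str  # "forward" | "backward"
    d_grid: np.ndarray  # in sweep order (increasing fwd, decreasing bwd)
    R: np.ndarray  # (M,)
    H: np.ndarray  # (M, N)
    HT: np.ndarray  # (M, N)
    sigma_f: np.ndarray  # (M, N)
    ac1: np.ndarray  # (M, N)
    n_obs: np.ndarray  # (M, N) entropy-input samples per node
    seed: int | None = None
    family: str = ""
    partial: bool = False  # True if the sweep aborted mid-grid
    meta: dict = field(default_factory=dict)


class CriticalPoint(NamedTuple):
    coupling: float
    explosive: bool
    index: int


def order_parameter(phases) -> float:
    """Time-averaged Kuramoto order parameter R = <|mean_j e^{i theta_j}|>_t.

    ``phases`` is (T, N): one row per time sample, one column per node.
    R = 1 for identical phases; R -> 0 for phases spread evenly on the
    circle.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    if phases.shape[0] < 1 or phases.shape[1] < 1:
        raise ValueError("phases must be a non-empty (T, N) array")
    return float(np.mean(np.abs(np.mean(np.exp(1j * phases), axis=1))))


def _entropy_inputs(run: SimulationRun, spike_threshold: float) -> list[np.ndarray]:
    """Per-node scalar series feeding the ordinal analysis."""
    if run.family == "kuramoto":
        return [run.observables[:, i] for i in range(run.observables.shape[1])]
    if run.family == "chialvo":
        return [
            poincare_section(
                run.observables[:, i], kind="maxima", threshold=spike_threshold
            ).values
            for i in range(run.observables.shape[1])
        ]
    if run.family == "rossler":
        return list(run.observables)
    raise ValueError(f"unknown family {run.family!r}")


def _phases_and_R(run: SimulationRun, spike_threshold: float) -> float:
    if run.family == "chialvo":
        T, N = run.observables.shape
        ph = np.full((T, N), np.nan)
        for i in range(N):
            try:
                ph[:, i] = chialvo_phase(
                    run.observables[:, i], spike_threshold=spike_threshold
                )
            except ValueError:
                return np.nan  # a silent node: phase (and R) undefined
        valid = np.all(np.isfinite(ph), axis=1)
        if not valid.any():
            return np.nan
        return order_parameter(ph[valid])
    return order_parameter(run.phases)


def _simulate(family, net, het, d, state, seed, sim_kwargs):
    if family == "kuramoto":
        return simulate_kuramoto(
            net, het, d, theta0=None if state is None else state[0],
            seed=seed, **sim_kwargs,
        )
    if family == "chialvo":
        return simulate_chialvo(
            net, het, d, state0=state, seed=seed, **sim_kwargs
        )
    if family == "rossler":
        return simulate_rossler(
            net, het, d, state0=None if state is None else state[0],
            seed=seed, **sim_kwargs,
        )
    raise ValueError(f"unknown family {family!r}")


def _synchronized_state(family, net, seed):
    """Initial condition near synchrony for the backward continuation."""
    rng = np.random.default_rng(seed)
    N = net.n_nodes
    if family == "kuramoto":
        return (rng.normal(0.0, 0.01, size=N),)
    if family == "chialvo":
        x = np.full(N, 1.0) + rng.normal(0.0, 1e-3, size=N)
        y = np.full(N, 1.5) + rng.normal(0.0, 1e-3, size=N)
        return (x, y)
    if family == "rossler":
        base = np.array([5.0, 5.0, 0.1])
        return (base[None, :] + rng.normal(0.0, 1e-3, size=(N, 3)),)
    raise ValueError(f"unknown family {family!r}")


def run_sweep(
    net: NetworkSpec,
    family: str,
    het: np.ndarray,
    d_grid,
    direction: str = "forward",
    seed: int | None = None,
    sim_kwargs: dict | None = None,
    D: int = 3,
    tau: int = 1,
    block_mode: str = "disjoint",
    spike_threshold: float = 0.5,
) -> SweepResult:
    """Run one forward or backward continuation in the coupling ``d``.

    ``het`` is the per-node heterogeneity vector (natural frequencies, bias
    currents or Rössler w, depending on ``family``).  The final state at
    each grid point seeds the next one; a backward sweep starts from a
    near-synchronous state at its first (largest) coupling.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be forward or backward, got {direction!r}")
    d_grid = np.sort(np.asarray(d_grid, dtype=float))
    if direction == "backward":
        d_grid = d_grid[::-1]
    M, N = len(d_grid), net.n_nodes
    out = SweepResult(
        direction=direction,
        d_grid=d_grid.copy(),
        R=np.full(M, np.nan),
        H=np.full((M, N), np.nan),
        HT=np.full((M, N), np.nan),
        sigma_f=np.full((M, N), np.nan),
        ac1=np.full((M, N), np.nan),
        n_obs=np.zeros((M, N), dtype=np.int64),
        seed=seed,
        family=family,
        meta={"D": D, "tau": tau, "block_mode": block_mode},
    )
    if M == 0:
        return out
    sim_kwargs = dict(sim_kwargs or {})
    state = None if direction == "forward" else _synchronized_state(
        family, net, seed
    )
    for j, d in enumerate(d_grid):
        try:
            run = _simulate(family, net, het, float(d), state, seed, sim_kwargs)
        except (ValueError, FloatingPointError) as exc:
            warnings.warn(
                f"sweep aborted at d={d:g}: {exc}", stacklevel=2
            )
            out.partial = True
            break
        state = run.final_state
        out.R[j] = _phases_and_R(run, spike_threshold)
        series = _entropy_inputs(run, spike_threshold)
        for i, xi in enumerate(series):
            out.n_obs[j, i] = len(xi)
            if len(xi) >= tau * D * 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # short-series guard
                    h, ht = opt_entropy_of_series(
                        xi, D=D, tau=tau, block_mode=block_mode
                    )
                out.H[j, i] = h
                out.HT[j, i] = ht
            if len(xi) >= 2:
                out.sigma_f[j, i] = fluctuation_std(xi)
                try:
                    out.ac1[j, i] = autocorrelation_lag(xi, 1)
                except (ValueError, ZeroDivisionError):
                    pass
    return out


def critical_coupling(sr: SweepResult, jump_threshold: float = 0.4) -> CriticalPoint:
    """Coupling of the first single-step jump of R exceeding
    ``jump_threshold`` (drop, for a backward sweep).

    If no step exceeds the threshold the sweep is flagged non-explosive and
    the coupling of the largest step is returned (first index on ties).
    """
    if len(sr.d_grid) < 2:
        raise ValueError("need at least 2 grid points")
    dR = np.diff(sr.R)
    if sr.direction == "backward":
        dR = -dR  # a desynchronization drop counts positive
    big = np.nonzero(dR > jump_threshold)[0]
    if len(big) > 0:
        j = big[0] + 1
        return CriticalPoint(float(sr.d_grid[j]), True, int(j))
    j = int(np.nanargmax(dR)) + 1
    return CriticalPoint(float(sr.d_grid[j]), False, int(j))


def hysteresis_width(
    forward: SweepResult,
    backward: SweepResult,
    jump_threshold: float = 0.4,
) -> float | None:
    """Width of the bistable window: d_c(forward) - d_c(backward), floored
    at 0.  Returns None when either sweep is non-explosive."""
    cf = critical_coupling(forward, jump_threshold)
    cb = critical_coupling(backward, jump_threshold)
    if not (cf.explosive and cb.explosive):
        return None
    return max(0.0, cf.coupling - cb.coupling)


def average_sweeps(results: list[SweepResult]) -> SweepResult:
    """Element-wise mean over realizations (identical grids required)."""
    if not results:
        raise ValueError("no sweeps to average")
    g0 = results[0].d_grid
    for r in results[1:]:
        if not np.array_equal(r.d_grid, g0):
            raise ValueError("sweeps have different coupling grids")
    def m(attr):
        return np.nanmean(np.stack([getattr(r, attr) for r in results]), axis=0)
    return SweepResult(
        direction=results[0].direction,
        d_grid=g0.copy(),
        R=m("R"), H=m("H"), HT=m("HT"),
        sigma_f=m("sigma_f"), ac1=m("ac1"),
        n_obs=np.stack([r.n_obs for r in results]).mean(axis=0),
        seed=None,
        family=results[0].family,
        partial=any(r.partial for r in results),
        meta={**results[0].meta, "n_realizations": len(results)},
    )
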