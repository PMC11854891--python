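"""Early-warning indicators: degree-class entropy averages, the hub-vs-leaf
alarm rule, comparator statistics, and the sentinel degree cutoff.

The working hypothesis is that on heterogeneous graphs with degree-correlated
node parameters, the highest-degree nodes (hubs) feel the approach of an
explosive synchronization transition long before the order parameter moves,
and that their ordinal transition entropy HT rises while low-degree nodes
stay at baseline.  The alarm rule operationalizes "the hub entropy departs
from the low-coupling baseline": it fires at the first coupling where the
hub-minus-reference entropy difference exceeds the baseline mean by
``n_sigma`` baseline standard deviations and stays there for a configurable
number of consecutive grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KClassProfile",
    "EwsTrace",
    "k_class_average",
    "fluctuation_std",
    "autocorrelation_lag",
    "ews_alarm",
    "degree_cutoff",
    "build_ews_trace",
]


@dataclass(frozen=True)
class KClassProfile:
    """Degree-class averages of a per-node quantity at one coupling."""

    degrees: np.ndarray  # distinct degrees, ascending
    sizes: np.ndarray  # class sizes N_k
    means: np.ndarray  # class means, aligned with ``degrees``
    coupling: float | None = None

    def mean(self, k: int) -> float:
        idx = np.nonzero(self.degrees == k)[0]
        if len(idx) == 0:
            raise KeyError(f"no nodes of degree {k}")
        return float(self.means[idx[0]])


@dataclass
class EwsTrace:
    """Hub- vs reference-class indicator series along a coupling grid."""

    d_grid: np.ndarray
    hub: np.ndarray  # highest-degree-class series
    reference: np.ndarray  # lowest-degree-class series
    comparators: dict = field(default_factory=dict)  # e.g. sigma_f, ac1

    @property
    def delta(self) -> np.ndarray:
        return self.hub - self.reference


def k_class_average(values, degrees, coupling: float | None = None) -> KClassProfile:
    """Arithmetic mean of a per-node quantity within each distinct degree."""
    values = np.asarray(values, dtype=float)
    degrees = np.asarray(degrees)
    if values.shape != degrees.shape:
        raise ValueError(
            f"need one value per node: {values.shape} vs {degrees.shape}"
        )
    ks = np.unique(degrees)
    sizes = np.array([(degrees == k).sum() for k in ks])
    means = np.array([values[degrees == k].mean() for k in ks])
    return KClassProfile(degrees=ks, sizes=sizes, means=means, coupling=coupling)


def fluctuation_std(x) -> float:
    """Population standard deviation of a series (the amplitude of its
    fluctuations around the mean)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    # clip tiny negative rounding residue for near-constant series
    return float(np.sqrt(max(0.0, np.mean(x * x) - np.mean(x) ** 2)))


def autocorrelation_lag(x, l: int = 1, centered: bool = False) -> float:
    """Normalized lag-l autocorrelation.

    By default this is the *uncentered* normalized inner product
    ``sum x(t) x(t+l) / sqrt(sum x(t)^2 * sum x(t+l)^2)`` over the
    overlapping window; set ``centered=True`` for the conventional
    mean-subtracted estimator.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= l:
        raise ValueError(f"need more than {l} samples for lag {l}")
    a, b = x[:-l], x[l:]
    if centered:
        a = a - a.mean()
        b = b - b.mean()
    norm = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if norm == 0:
        raise ZeroDivisionError("zero-norm window: autocorrelation undefined")
    return float(np.sum(a * b) / norm)


def ews_alarm(
    trace: EwsTrace,
    n_sigma: float = 3.0,
    baseline_points: int = 3,
    persistence: int = 2,
) -> float | None:
    """First coupling at which the hub-minus-reference entropy difference
    departs from its low-coupling baseline.

    The baseline mean and SD are estimated from the first
    ``baseline_points`` grid points (the weakest couplings); the alarm fires
    at the first grid point where the difference exceeds
    ``baseline mean + n_sigma * SD`` and stays above for ``persistence``
    consecutive points.  Returns None when the difference never departs.
    """
    d_grid = np.asarray(trace.d_grid, dtype=float)
    if len(d_grid) < 5:
        raise ValueError("need at least 5 grid points to estimate a baseline")
    delta = trace.delta
    base = delta[:baseline_points]
    thresh = base.mean() + n_sigma * base.std()
    above = delta > thresh
    for j in range(baseline_points, len(d_grid) - persistence + 1):
        if above[j : j + persistence].all():
            return float(d_grid[j])
    return None


def degree_cutoff(
    profile_low: KClassProfile,
    profile_near: KClassProfile,
    margin: float = 0.05,
) -> int | None:
    """Smallest degree above which the near-transition entropy exceeds the
    low-coupling one by more than ``margin`` for every larger observed class.

    Nodes above the cutoff are the candidate sentinel nodes.  Returns None
    when no class clears the margin all the way up.
    """
    if not np.array_equal(profile_low.degrees, profile_near.degrees):
        raise ValueError("profiles must share the same degree support")
    diff = profile_near.means - profile_low.means
    exceeds = diff > margin
    # suffix-and: class k qualifies only if all classes >= k also do
    for j in range(len(exceeds)):
        if exceeds[j:].all():
            return int(profile_low.degrees[j])
    return None


def build_ews_trace(
    sweep,
    degrees,
    measure: str = "HT",
) -> EwsTrace:
    """Hub-class vs lowest-degree-class trace of a per-node sweep measure.

    ``sweep`` is a :class:`~optews.sweep.SweepResult` (or averaged result);
    the hub class is the maximum observed degree, the reference the minimum
    (on scale-free graphs, the modal low-degree class, averaging many nodes).
    """
    degrees = np.asarray(degrees)
    values = getattr(sweep, measure)
    k_hi, k_lo = degrees.max(), degrees.min()
    hub = values[:, degrees == k_hi].mean(axis=1)
    ref = values[:, degrees == k_lo].mean(axis=1)
    comparators = {
        name: getattr(sweep, name)[:, degrees == k_hi].mean(axis=1)
        for name in ("sigma_f", "ac1")
        if hasattr(sweep, name)
    }
    return EwsTrace(
        d_grid=np.asarray(sweep.d_grid, float),
        hub=hub,
        reference=ref,
        comparators=comparators,
    )
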