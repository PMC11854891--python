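"""Network topologies and degree-correlated node heterogeneity.

Explosive synchronization is induced on heterogeneous graphs (stars and
scale-free networks) by correlating each node's intrinsic time scale — the
Kuramoto natural frequency, the Chialvo bias current, or the Rössler
frequency parameter — with its degree.  Star leaves additionally receive a
small quenched disorder so that backward (desynchronization) sweeps do not
get stuck in a persistent synchronous state.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "NetworkSpec",
    "build_star",
    "build_scale_free",
    "kuramoto_frequencies",
    "chialvo_currents",
    "rossler_frequencies",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Undirected, unweighted graph with degree bookkeeping."""

    n_nodes: int
    adjacency: np.ndarray  # symmetric 0/1, zero diagonal
    degrees: np.ndarray
    topology_label: str
    seed: int | None = None

    @property
    def k_max(self) -> int:
        return int(self.degrees.max())

    @property
    def hub(self) -> int:
        """Index of (a) maximum-degree node; ties broken by lowest index."""
        return int(np.argmax(self.degrees))

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style neighbor lists (indptr, indices) for the integrators."""
        nbr = [np.nonzero(self.adjacency[i])[0] for i in range(self.n_nodes)]
        indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        indptr[1:] = np.cumsum([len(x) for x in nbr])
        indices = (
            np.concatenate(nbr).astype(np.int64)
            if indptr[-1] > 0
            else np.zeros(0, dtype=np.int64)
        )
        return indptr, indices


def _from_graph(g: nx.Graph, label: str, seed: int | None) -> NetworkSpec:
    g = nx.convert_node_labels_to_integers(g)
    A = nx.to_numpy_array(g, dtype=np.int8)
    return NetworkSpec(
        n_nodes=g.number_of_nodes(),
        adjacency=A,
        degrees=A.sum(axis=1).astype(np.int64),
        topology_label=label,
        seed=seed,
    )


def build_star(N: int) -> NetworkSpec:
    """Star of ``N`` nodes: hub at index 0 with degree N-1, leaves degree 1."""
    if N < 3:
        raise ValueError(f"a star needs N >= 3 nodes, got {N}")
    return _from_graph(nx.star_graph(N - 1), f"star-{N}", None)


def _truncated_powerlaw_degrees(
    N: int, mean_degree: float, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Degree sequence ~ k^-gamma on [k_min, sqrt(N*<k>)], k_min set so the
    truncated-law mean is closest to the target."""
    k_cap = max(3, int(np.sqrt(N * mean_degree)))
    best_kmin, best_err = 1, np.inf
    for k_min in range(1, min(6, k_cap)):
        ks = np.arange(k_min, k_cap + 1, dtype=float)
        w = ks**-gamma
        mu = (ks * w).sum() / w.sum()
        if abs(mu - mean_degree) < best_err:
            best_kmin, best_err = k_min, abs(mu - mean_degree)
    ks = np.arange(best_kmin, k_cap + 1)
    w = ks.astype(float) ** -gamma
    seq = rng.choice(ks, size=N, p=w / w.sum())
    if seq.sum() % 2:  # handshake lemma: total degree must be even
        seq[rng.integers(N)] += 1
    return seq


def build_scale_free(
    N: int,
    mean_degree: float = 4.0,
    gamma: float = 2.25,
    seed: int | None = None,
    max_attempts: int = 100,
) -> NetworkSpec:
    """Configuration-model scale-free graph, simplified to its largest
    connected component.

    Degrees are drawn from a truncated power law ``p(k) ~ k^-gamma``;
    self-loops and parallel edges are discarded, then the largest component
    is kept.  A draw is accepted when the realized mean degree is within 15%
    of the target and at least 90% of the nodes survive.
    """
    if N < 10:
        raise ValueError(f"scale-free construction needs N >= 10, got {N}")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        seq = _truncated_powerlaw_degrees(N, mean_degree, gamma, rng)
        g = nx.configuration_model(seq, seed=int(rng.integers(2**31)))
        g = nx.Graph(g)  # drop parallel edges
        g.remove_edges_from(nx.selfloop_edges(g))
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp).copy()
        realized = 2 * g.number_of_edges() / g.number_of_nodes()
        if (
            abs(realized - mean_degree) <= 0.15 * mean_degree
            and g.number_of_nodes() >= 0.9 * N
        ):
            return _from_graph(g, f"sf-{N}-g{gamma}", seed)
    raise RuntimeError(
        f"could not realize a scale-free graph with N={N}, <k>={mean_degree}, "
        f"gamma={gamma} in {max_attempts} attempts"
    )


def kuramoto_frequencies(
    net: NetworkSpec,
    rng: np.random.Generator,
    hub_frequency: float = 1.3,
    leaf_base: float = 1.0,
    leaf_disorder: float = 0.005,
) -> np.ndarray:
    """Natural frequencies for a Kuramoto star: hub at 1.3, leaves at
    1 + 0.005*eps with eps ~ U(0,1).

    The hub/leaf frequency gap dynamically isolates the hub, which is what
    makes the transition explosive; the tiny leaf disorder breaks exact
    degeneracy among leaves.
    """
    omega = np.full(net.n_nodes, leaf_base) + leaf_disorder * rng.uniform(
        size=net.n_nodes
    )
    omega[net.hub] = hub_frequency
    return omega


def chialvo_currents(
    net: NetworkSpec,
    rng: np.random.Generator,
    baseline: float = 0.049,
    alpha: float = 3e-5,
    star_hub_current: float = 0.050,
    star_leaf_disorder: float = 1e-4,
) -> np.ndarray:
    """Bias currents for Chialvo maps, correlated with degree.

    On a star: hub I = 0.050 and leaves I = 0.049 + 1e-4*eps, eps ~ U(0,1).
    Otherwise the linear degree rule I_i = 0.049 + alpha*k_i (alpha = 3e-5).
    """
    if net.topology_label.startswith("star"):
        I = baseline + star_leaf_disorder * rng.uniform(size=net.n_nodes)
        I[net.hub] = star_hub_current
        return I
    return baseline + alpha * net.degrees.astype(float)


def rossler_frequencies(
    net: NetworkSpec,
    rng: np.random.Generator,
    baseline: float = 1.06,
    alpha: float = 2.73e-4,
    star_leaf_disorder: float = 1e-4,
) -> np.ndarray:
    """Rössler frequency parameters w_i = 1.06 + alpha*k_i (alpha=2.73e-4).

    On a star the leaves additionally get a U(0, xi) jitter (xi small, default
    1e-4) so the backward route actually desynchronizes.
    """
    w = baseline + alpha * net.degrees.astype(float)
    if net.topology_label.startswith("star"):
        jitter = star_leaf_disorder * rng.uniform(size=net.n_nodes)
        jitter[net.hub] = 0.0
        w = w + jitter
    return w
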