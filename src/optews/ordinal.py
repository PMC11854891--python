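"""Ordinal-pattern symbolization and entropy measures.

A scalar series is split into blocks of ``D`` lagged samples; each block is
mapped to the permutation that sorts it ascending, identified by its 1-based
lexicographic rank among the ``D!`` permutations.  From the resulting symbol
stream we compute the ordinal-pattern probability distribution, its normalized
permutation entropy ``H``, the pattern-to-pattern transition matrix, and the
ordinal-pattern transition (OPT) entropy ``HT`` — the average over all ``D!``
patterns of the normalized Shannon entropy of each pattern's successor
distribution.  A Poincare-section helper extracts local extrema so that
amplitude series of spikes or oscillation minima can be symbolized instead of
the raw signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SymbolSequence",
    "PatternDistribution",
    "TransitionMatrix",
    "PoincareSeries",
    "encode_patterns",
    "pattern_distribution",
    "permutation_entropy",
    "normalized_permutation_entropy",
    "transition_matrix",
    "local_pattern_entropy",
    "opt_entropy",
    "opt_entropy_of_series",
    "poincare_section",
    "pattern_table",
]

_MAX_D = 7

# Minimum block count below which pattern statistics are unreliable,
# expressed as a multiple of the alphabet size D!.
MIN_BLOCKS_PER_PATTERN = 10


@dataclass(frozen=True)
class SymbolSequence:
    """Ordinal symbols (1-based lexicographic ranks) with their metadata."""

    symbols: np.ndarray
    D: int
    tau: int
    block_mode: str  # "disjoint" | "overlapping"

    @property
    def L(self) -> int:
        return len(self.symbols)

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.D)


@dataclass(frozen=True)
class PatternDistribution:
    """Relative frequency of each of the D! ordinal patterns."""

    probs: np.ndarray
    counts: np.ndarray
    D: int


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix of pattern-to-pattern transition probabilities.

    Entry ``(l, m)`` (0-based here; patterns are labelled 1-based elsewhere)
    is the conditional probability that pattern ``m+1`` immediately follows
    pattern ``l+1``.  Rows of patterns never observed as a transition source
    are identically zero.
    """

    probs: np.ndarray
    pattern_counts: np.ndarray
    D: int


@dataclass(frozen=True)
class PoincareSeries:
    """Amplitudes and positions of strict local extrema of a signal."""

    values: np.ndarray
    indices: np.ndarray
    kind: str  # "maxima" | "minima"
    threshold: float | None = None

    def __len__(self) -> int:
        return len(self.values)


def _lehmer_ranks(blocks: np.ndarray) -> np.ndarray:
    """1-based lexicographic rank of the stable sorting permutation per row."""
    D = blocks.shape[1]
    # stable argsort: ties keep temporal order, earlier sample gets lower rank
    perm = np.argsort(blocks, axis=1, kind="stable")
    ranks = np.zeros(blocks.shape[0], dtype=np.int64)
    for j in range(D):
        # Lehmer digit: number of remaining elements smaller than perm[:, j]
        smaller = np.zeros(blocks.shape[0], dtype=np.int64)
        for j2 in range(j + 1, D):
            smaller += perm[:, j2] < perm[:, j]
        ranks = ranks * (D - j) + smaller
    return ranks + 1


def encode_patterns(
    x,
    D: int = 3,
    tau: int = 1,
    block_mode: str = "disjoint",
) -> SymbolSequence:
    """Symbolize a scalar series into ordinal patterns.

    Parameters
    ----------
    x : array-like
        Scalar time series.
    D : int
        Pattern length (embedding dimension), ``2 <= D <= 7``.
    tau : int
        Lag between the samples of a block.
    block_mode : str
        ``"disjoint"`` advances by ``tau*D`` samples per block, giving
        ``L = floor(T/(tau*D))`` blocks; ``"overlapping"`` advances by one
        sample (stride-1 Bandt-Pompe), giving ``L = T - (D-1)*tau``.

    Returns
    -------
    SymbolSequence
        Symbols in ``[1, D!]``, one per block.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a one-dimensional scalar series")
    if not (2 <= D <= _MAX_D):
        raise ValueError(f"D must be in [2, {_MAX_D}], got {D}")
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    if block_mode not in ("disjoint", "overlapping"):
        raise ValueError(f"unknown block_mode {block_mode!r}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    T = len(x)
    if block_mode == "disjoint":
        L = T // (tau * D)
        if L < 1:
            raise ValueError(
                f"series of length {T} too short for one disjoint block "
                f"(needs >= {tau * D} samples)"
            )
        starts = np.arange(L) * (tau * D)
    else:
        L = T - (D - 1) * tau
        if L < 1:
            raise ValueError(
                f"series of length {T} too short for one overlapping block "
                f"(needs >= {(D - 1) * tau + 1} samples)"
            )
        starts = np.arange(L)
    idx = starts[:, None] + np.arange(D)[None, :] * tau
    symbols = _lehmer_ranks(x[idx])
    nfact = math.factorial(D)
    if L < MIN_BLOCKS_PER_PATTERN * nfact:
        warnings.warn(
            f"only {L} blocks for {nfact} patterns; pattern statistics may be "
            f"unreliable (recommended L >= {MIN_BLOCKS_PER_PATTERN * nfact})",
            stacklevel=2,
        )
    return SymbolSequence(symbols=symbols, D=D, tau=tau, block_mode=block_mode)


def pattern_distribution(s: SymbolSequence) -> PatternDistribution:
    """Counts-normalized probability of each of the D! ordinal patterns."""
    if s.L == 0:
        raise ValueError("empty symbol sequence")
    nfact = s.n_patterns
    counts = np.bincount(s.symbols - 1, minlength=nfact).astype(np.int64)
    return PatternDistribution(probs=counts / s.L, counts=counts, D=s.D)


def _shannon_nats(p: np.ndarray) -> float:
    p = p[p > 0]
    return max(0.0, float(-np.sum(p * np.log(p))))


def permutation_entropy(P: PatternDistribution) -> float:
    """Shannon entropy of the pattern distribution, in nats (0*ln 0 := 0)."""
    return _shannon_nats(P.probs)


def normalized_permutation_entropy(P: PatternDistribution) -> float:
    """Permutation entropy divided by its maximum ln(D!); lies in [0, 1]."""
    return permutation_entropy(P) / math.log(math.factorial(P.D))


def transition_matrix(s: SymbolSequence) -> TransitionMatrix:
    """Conditional probabilities of consecutive ordinal-pattern pairs.

    Self-transitions count.  Source counts exclude the final symbol (it has
    no successor); a pattern never seen as a source keeps an all-zero row.
    """
    if s.L < 2:
        raise ValueError("need at least 2 symbols for a transition matrix")
    nfact = s.n_patterns
    src = s.symbols[:-1] - 1
    dst = s.symbols[1:] - 1
    pair_counts = np.zeros((nfact, nfact), dtype=np.int64)
    np.add.at(pair_counts, (src, dst), 1)
    pattern_counts = np.bincount(src, minlength=nfact).astype(np.int64)
    probs = np.zeros((nfact, nfact), dtype=float)
    observed = pattern_counts > 0
    probs[observed] = pair_counts[observed] / pattern_counts[observed, None]
    return TransitionMatrix(probs=probs, pattern_counts=pattern_counts, D=s.D)


def local_pattern_entropy(M: TransitionMatrix, pattern: int) -> float:
    """Normalized entropy of the successor distribution of one pattern.

    ``pattern`` is the 1-based pattern label.  Unobserved patterns (all-zero
    row) return 0.
    """
    nfact = math.factorial(M.D)
    if not (1 <= pattern <= nfact):
        raise IndexError(f"pattern label must be in [1, {nfact}], got {pattern}")
    return _shannon_nats(M.probs[pattern - 1]) / math.log(nfact)


def opt_entropy(M: TransitionMatrix) -> float:
    """Ordinal-pattern transition entropy HT: plain average of the D! local
    successor entropies.

    Unobserved patterns contribute zero terms, so missing patterns deflate
    HT; this is deliberate, as it makes HT sensitive to how much of the
    pattern alphabet the dynamics visits.
    """
    nfact = math.factorial(M.D)
    logZ = math.log(nfact)
    total = 0.0
    for row in M.probs:
        total += _shannon_nats(row) / logZ
    return total / nfact


def opt_entropy_of_series(
    x,
    D: int = 3,
    tau: int = 1,
    block_mode: str = "disjoint",
) -> tuple[float, float]:
    """Convenience: (H, HT) of a scalar series in one call."""
    s = encode_patterns(x, D=D, tau=tau, block_mode=block_mode)
    H = normalized_permutation_entropy(pattern_distribution(s))
    HT = opt_entropy(transition_matrix(s))
    return H, HT


def poincare_section(
    x,
    kind: str = "maxima",
    threshold: float | None = None,
    smooth: int | None = None,
) -> PoincareSeries:
    """Strict local extrema of a signal, as a discrete amplitude series.

    A maximum at position ``i`` requires ``x[i-1] < x[i] > x[i+1]`` strictly
    (minima mirrored); plateaus therefore yield no extremum.  An optional
    ``threshold`` keeps only maxima with value above it (below it, for
    minima) — used e.g. to retain spikes of a membrane-potential series.
    ``smooth`` applies a centered moving average of that width first, for
    noisy (e.g. experimental) recordings.  An input with no extrema returns
    an empty series, not an error.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-d series of length >= 3")
    if smooth is not None and smooth > 1:
        kernel = np.full(smooth, 1.0 / smooth)
        x = np.convolve(x, kernel, mode="valid")
    if kind not in ("maxima", "minima"):
        raise ValueError(f"kind must be 'maxima' or 'minima', got {kind!r}")
    a, b, c = x[:-2], x[1:-1], x[2:]
    if kind == "maxima":
        mask = (b > a) & (b > c)
    else:
        mask = (b < a) & (b < c)
    idx = np.nonzero(mask)[0] + 1
    vals = x[idx]
    if threshold is not None:
        keep = vals > threshold if kind == "maxima" else vals < threshold
        idx, vals = idx[keep], vals[keep]
    return PoincareSeries(values=vals, indices=idx, kind=kind, threshold=threshold)


def pattern_table(D: int = 3) -> list[tuple[int, tuple[int, ...]]]:
    """Mapping from 1-based pattern label to its permutation, lexicographic.

    The permutation lists the within-block positions in ascending order of
    value, e.g. for D=3 the label 1 is (0, 1, 2): a monotonically increasing
    block.
    """
    import itertools

    return [
        (i + 1, perm)
        for i, perm in enumerate(itertools.permutations(range(D)))
    ]
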