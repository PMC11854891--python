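"""Ordinal symbolization and entropy measures.

The reference oracle here is a deliberately naive reimplementation with
plain Python loops (itertools permutation lookup, dict counting); the
package must agree with it exactly.
"""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optews.ordinal import (
    MIN_BLOCKS_PER_PATTERN,
    PatternDistribution,
    SymbolSequence,
    encode_patterns,
    local_pattern_entropy,
    normalized_permutation_entropy,
    opt_entropy,
    opt_entropy_of_series,
    pattern_distribution,
    pattern_table,
    permutation_entropy,
    poincare_section,
    transition_matrix,
)


# ---------------------------------------------------------------- oracle


def brute_symbols(x, D, tau, mode):
    """Naive symbolization: explicit block loop + permutation lookup."""
    perms = list(itertools.permutations(range(D)))
    T = len(x)
    if mode == "disjoint":
        starts = range(0, (T // (tau * D)) * tau * D, tau * D)
    else:
        starts = range(T - (D - 1) * tau)
    out = []
    for t in starts:
        block = [x[t + q * tau] for q in range(D)]
        # stable ascending order: sort (value, position) pairs
        order = tuple(
            i for _, i in sorted((v, i) for i, v in enumerate(block))
        )
        out.append(perms.index(order) + 1)
    return out


def brute_H_HT(symbols, D):
    """Naive entropies from a symbol list (dict counting, float loops)."""
    nfact = math.factorial(D)
    L = len(symbols)
    counts = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
    S = -sum((c / L) * math.log(c / L) for c in counts.values())
    H = S / math.log(nfact)
    pair = {}
    src = {}
    for a, b in zip(symbols[:-1], symbols[1:]):
        pair[(a, b)] = pair.get((a, b), 0) + 1
        src[a] = src.get(a, 0) + 1
    HT = 0.0
    for l in range(1, nfact + 1):
        if src.get(l, 0) == 0:
            continue
        row = [pair.get((l, m), 0) / src[l] for m in range(1, nfact + 1)]
        Hl = -sum(p * math.log(p) for p in row if p > 0) / math.log(nfact)
        HT += Hl
    return H, HT / nfact


# ----------------------------------------------------------- encoding


@pytest.mark.parametrize(
    "x, expected",
    [
        ([4.0, 7.0, 9.0], 1),  # fully ascending -> first permutation
        ([9.0, 7.0, 4.0], 6),  # fully descending -> last permutation
        ([1.0, 3.0, 2.0], 2),  # (0, 2, 1)
    ],
)
def test_single_block_rank(x, expected):
    s = encode_patterns(x, D=3, tau=1)
    assert list(s.symbols) == [expected]


def test_tie_break_earlier_sample_ranks_lower():
    # equal values: temporal order decides, so [1, 1, 0] sorts as
    # positions (2, 0, 1)
    s = encode_patterns([1.0, 1.0, 0.0], D=3, tau=1)
    perms = dict(pattern_table(3))
    assert perms[int(s.symbols[0])] == (2, 0, 1)


def test_block_counts_match_stated_formulas():
    x = np.arange(103, dtype=float)
    s_d = encode_patterns(x, D=3, tau=2, block_mode="disjoint")
    assert s_d.L == 103 // 6
    s_o = encode_patterns(x, D=3, tau=2, block_mode="overlapping")
    assert s_o.L == 103 - 2 * 2


def test_uniform_noise_visits_all_patterns_equally():
    rng = np.random.default_rng(42)
    x = rng.uniform(size=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = encode_patterns(x, D=3, tau=1, block_mode="disjoint")
    P = pattern_distribution(s)
    assert np.all(np.abs(P.probs - 1 / 6) < 0.05)


@pytest.mark.parametrize(
    "x, err",
    [
        ([1.0, 2.0], "too short"),
        ([1.0, np.nan, 2.0], "non-finite"),
    ],
)
def test_encode_rejects_bad_input(x, err):
    with pytest.raises(ValueError, match=err):
        encode_patterns(x, D=3, tau=1)


def test_short_series_warns_about_pattern_statistics():
    with pytest.warns(UserWarning, match="unreliable"):
        encode_patterns(np.random.default_rng(0).uniform(size=30), D=3)
    # long enough: no warning
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        encode_patterns(
            np.random.default_rng(0).uniform(size=MIN_BLOCKS_PER_PATTERN * 6 * 3),
            D=3,
        )


# --------------------------------------------------- distribution, H


def _seq(symbols, D=3):
    return SymbolSequence(np.asarray(symbols), D=D, tau=1, block_mode="disjoint")


@pytest.mark.parametrize(
    "symbols, probs",
    [
        ([1, 1, 1], (1, 0, 0, 0, 0, 0)),
        ([1, 2, 1, 2], (0.5, 0.5, 0, 0, 0, 0)),
    ],
)
def test_pattern_distribution_examples(symbols, probs):
    P = pattern_distribution(_seq(symbols))
    assert np.allclose(P.probs, probs)


def test_pattern_distribution_uniform_draw():
    rng = np.random.default_rng(7)
    P = pattern_distribution(_seq(rng.integers(1, 7, size=6000)))
    assert np.max(np.abs(P.probs - 1 / 6)) < 0.03


@pytest.mark.parametrize(
    "probs, S",
    [
        ((1, 0, 0, 0, 0, 0), 0.0),
        ((1 / 6,) * 6, math.log(6)),
        ((0.5, 0.5, 0, 0, 0, 0), math.log(2)),
    ],
)
def test_permutation_entropy_closed_forms(probs, S):
    P = PatternDistribution(np.array(probs, float), np.zeros(6, int), 3)
    assert permutation_entropy(P) == pytest.approx(S, abs=1e-12)
    assert normalized_permutation_entropy(P) == pytest.approx(
        S / math.log(6), abs=1e-12
    )


# -------------------------------------------------- transition matrix, HT


def test_two_cycle_transition_matrix():
    M = transition_matrix(_seq([1, 2, 1, 2, 1]))
    assert M.probs[0, 1] == 1.0 and M.probs[1, 0] == 1.0
    assert M.probs.sum() == 2.0
    assert opt_entropy(M) == 0.0


def test_self_transition_only():
    M = transition_matrix(_seq([1, 1, 1, 1]))
    assert M.probs[0, 0] == 1.0
    assert local_pattern_entropy(M, 1) == 0.0


def test_uniform_symbol_stream_rows_near_uniform():
    rng = np.random.default_rng(11)
    M = transition_matrix(_seq(rng.integers(1, 7, size=60000)))
    assert np.max(np.abs(M.probs - 1 / 6)) < 0.02
    assert opt_entropy(M) > 0.98


def test_one_observed_pattern_uniform_successors_gives_one_sixth():
    # symbol 1 always the source, successors cycle 1..6 uniformly: build a
    # stream 1,a,1,b,... is not possible with single source; instead craft
    # the matrix by a stream over pattern 1 only is degenerate. Use direct
    # row construction via a stream where pattern 3 has uniform successors
    # and every other row is unobserved: impossible in a single stream, so
    # test the averaging convention directly on a crafted matrix.
    from optews.ordinal import TransitionMatrix

    probs = np.zeros((6, 6))
    probs[2] = 1 / 6
    M = TransitionMatrix(probs=probs, pattern_counts=np.eye(6, dtype=np.int64)[2] * 6, D=3)
    assert local_pattern_entropy(M, 3) == pytest.approx(1.0)
    assert opt_entropy(M) == pytest.approx(1 / 6)


def test_local_pattern_entropy_half_half_row():
    from optews.ordinal import TransitionMatrix

    probs = np.zeros((6, 6))
    probs[0, :2] = 0.5
    M = TransitionMatrix(probs, np.array([2, 0, 0, 0, 0, 0]), 3)
    assert local_pattern_entropy(M, 1) == pytest.approx(
        math.log(2) / math.log(6)
    )
    with pytest.raises(IndexError):
        local_pattern_entropy(M, 7)


def test_transition_matrix_needs_two_symbols():
    with pytest.raises(ValueError):
        transition_matrix(_seq([1]))


# ------------------------------------------------------ oracle equivalence


@pytest.mark.parametrize("mode", ["disjoint", "overlapping"])
def test_matches_brute_force_on_random_series(mode):
    """Symbolization, H and HT agree exactly with the naive loop oracle."""
    rng = np.random.default_rng(123)
    for _ in range(30):
        n = int(rng.integers(30, 500))
        D = int(rng.integers(2, 5))
        tau = int(rng.integers(1, 3))
        x = rng.normal(size=n)
        if rng.random() < 0.3:  # inject ties
            x = np.round(x, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = encode_patterns(x, D=D, tau=tau, block_mode=mode)
        assert list(s.symbols) == brute_symbols(list(x), D, tau, mode)
        if s.L >= 2:
            H, HT = brute_H_HT(list(s.symbols), D)
            assert normalized_permutation_entropy(
                pattern_distribution(s)
            ) == pytest.approx(H, abs=1e-14)
            assert opt_entropy(transition_matrix(s)) == pytest.approx(
                HT, abs=1e-14
            )


# -------------------------------------------------------- invariants


@given(st.integers(0, 2**31 - 1), st.integers(40, 400))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_entropies_bounded_and_rows_stochastic(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = encode_patterns(x, D=3, tau=1)
    P = pattern_distribution(s)
    assert P.probs.sum() == pytest.approx(1.0, abs=1e-12)
    M = transition_matrix(s)
    observed = M.pattern_counts > 0
    assert np.allclose(M.probs[observed].sum(axis=1), 1.0, atol=1e-12)
    assert np.all(M.probs[~observed] == 0)
    H = normalized_permutation_entropy(P)
    HT = opt_entropy(M)
    assert 0 <= H <= 1 and 0 <= HT <= 1


@pytest.mark.parametrize("n", [10, 57, 300])
def test_monotone_series_has_zero_entropy(n):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        H, HT = opt_entropy_of_series(np.arange(n, dtype=float))
    assert H == 0.0 and HT == 0.0


def test_block_modes_agree_for_white_noise():
    rng = np.random.default_rng(5)
    x = rng.normal(size=100_000)
    Pd = pattern_distribution(encode_patterns(x, 3, 1, "disjoint"))
    Po = pattern_distribution(encode_patterns(x, 3, 1, "overlapping"))
    assert np.max(np.abs(Pd.probs - Po.probs)) < 0.01


# ----------------------------------------------------- Poincare section


def test_sinusoid_maxima_amplitudes():
    x = np.sin(0.1 * np.arange(1000))
    sec = poincare_section(x, kind="maxima")
    assert len(sec) > 10
    assert np.all(np.abs(sec.values - 1.0) < 1e-2)
    assert np.all(np.diff(sec.indices) > 0)


def test_monotone_series_has_no_extrema():
    assert len(poincare_section(np.arange(10.0), "maxima")) == 0


def test_plateau_yields_no_strict_maximum():
    assert len(poincare_section([0.0, 1.0, 1.0, 0.0], "maxima")) == 0


def test_threshold_gates_spike_maxima():
    x = np.array([0.0, 0.3, 0.0, 0.9, 0.0, 0.4, 0.0])
    sec = poincare_section(x, kind="maxima", threshold=0.5)
    assert list(sec.values) == [0.9]


def test_smoothing_removes_noise_extrema():
    rng = np.random.default_rng(0)
    t = np.arange(2000)
    x = np.sin(0.05 * t) + 0.05 * rng.normal(size=2000)
    raw = poincare_section(x, kind="maxima")
    smoothed = poincare_section(x, kind="maxima", smooth=15)
    true_count = 0.05 * 2000 / (2 * np.pi)
    assert len(raw) > 2 * true_count  # noise-dominated
    # smoothing suppresses most spurious extrema but keeps every true one
    assert true_count <= len(smoothed) < len(raw) / 5


def test_minima_mirror_maxima():
    x = np.sin(0.1 * np.arange(500))
    sec = poincare_section(x, kind="minima")
    assert np.all(sec.values < -0.99)
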