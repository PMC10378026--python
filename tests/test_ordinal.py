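"""Ordinal symbolization and permutation entropy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petd.ordinal import (
    OrdinalConfig,
    TimeSeries,
    index_to_pattern,
    ordinal_pattern,
    pattern_distribution,
    pattern_to_index,
    pe_curve,
    permutation_entropy,
    symbolize,
)

from conftest import tiled_sine


def naive_counts(x, D, tau):
    """Reference path: per-window stable argsort + dictionary counting."""
    n = len(x) - (D - 1) * tau
    counts = np.zeros(math.factorial(D), dtype=np.int64)
    for i in range(n):
        w = np.asarray([x[i + k * tau] for k in range(D)], dtype=float)
        pat = tuple(int(j) for j in np.argsort(w, kind="stable"))
        counts[pattern_to_index(pat)] += 1
    return counts


def entropy_of_counts(counts):
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


@pytest.mark.parametrize(
    "window, expected",
    [
        ([1.2, 3.4, 2.1], (0, 2, 1)),
        ([5, 5, 5], (0, 1, 2)),  # stable tie-break -> identity
        ([9, 4, 1], (2, 1, 0)),
        ([2, 1, 1, 3], (1, 2, 0, 3)),  # tie between equal middles
    ],
)
def test_ordinal_pattern_examples(window, expected):
    assert ordinal_pattern(window) == expected


def test_ordinal_pattern_rejects_nonfinite():
    with pytest.raises(ValueError, match="finite"):
        ordinal_pattern([1.0, np.nan, 2.0])


@pytest.mark.parametrize("D", [2, 3, 4, 5])
def test_pattern_index_bijection(D):
    import itertools

    seen = set()
    for perm in itertools.permutations(range(D)):
        idx = pattern_to_index(perm)
        assert index_to_pattern(idx, D) == perm
        seen.add(idx)
    assert seen == set(range(math.factorial(D)))


def test_pattern_index_lexicographic_order():
    # identity is rank 0, full reversal is rank D!-1
    assert pattern_to_index((0, 1, 2, 3)) == 0
    assert pattern_to_index((3, 2, 1, 0)) == 23


@pytest.mark.parametrize(
    "values, D, tau, n_expected",
    [
        ([1, 2, 3, 4], 3, 1, 2),
        ([1, 2, 3, 4, 5, 6], 3, 2, 2),
        (list(range(1000)), 5, 1, 996),
    ],
)
def test_symbolize_counts(values, D, tau, n_expected):
    ts = TimeSeries(np.asarray(values, float), fs=1.0)
    sym = symbolize(ts, OrdinalConfig(D, tau))
    assert len(sym) == n_expected
    assert sym.min() >= 0 and sym.max() < math.factorial(D)


def test_symbolize_too_short_names_minimum():
    ts = TimeSeries(np.arange(5.0), fs=1.0)
    with pytest.raises(ValueError, match="N >= 9"):
        symbolize(ts, OrdinalConfig(D=3, tau=4))


def test_pattern_distribution_examples():
    d = pattern_distribution(np.zeros(10, dtype=int), D=3)
    assert d.probs[0] == 1.0 and d.probs[1:].sum() == 0.0
    d = pattern_distribution(np.arange(6), D=3)
    assert np.allclose(d.probs, 1 / 6)
    ts = TimeSeries(np.array([1.0, 2, 3, 4]), fs=1.0)
    sym = symbolize(ts, OrdinalConfig(3, 1))
    d = pattern_distribution(sym, D=3)
    assert d.probs[pattern_to_index((0, 1, 2))] == 1.0
    assert d.n_symbols == 2
    with pytest.raises(ValueError):
        pattern_distribution(np.array([], dtype=int), D=3)


@pytest.mark.parametrize(
    "values",
    [np.full(100, 3.7), np.arange(100.0), np.exp(np.linspace(0, 5, 80))],
)
def test_pe_zero_for_single_pattern_series(values):
    """Constant and strictly monotone series produce one pattern: PE = 0."""
    ts = TimeSeries(values, fs=1.0)
    assert permutation_entropy(ts, OrdinalConfig(4, 2)) == 0.0


def test_pe_iid_noise_approaches_log_dfactorial(rng):
    """Exchangeable iid data make all D! patterns equiprobable."""
    ts = TimeSeries(rng.standard_normal(100_000), fs=1.0)
    pe = permutation_entropy(ts, OrdinalConfig(3, 1))
    assert abs(pe - np.log(6)) < 0.01


def test_vectorized_pe_matches_naive_oracle(rng):
    """Bit-exact agreement with dictionary counting on 100 random instances."""
    for _ in range(100):
        D = int(rng.integers(2, 6))
        tau = int(rng.integers(1, 4))
        n = int(rng.integers((D - 1) * tau + 1, 201))
        x = rng.standard_normal(n)
        if rng.random() < 0.3:  # provoke ties
            x = np.round(x, 1)
        ts = TimeSeries(x, fs=1.0)
        cfg = OrdinalConfig(D, tau)
        sym = symbolize(ts, cfg)
        counts = pattern_distribution(sym, D).counts
        ref = naive_counts(x, D, tau)
        assert np.array_equal(counts, ref)
        assert permutation_entropy(ts, cfg) == entropy_of_counts(ref)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    # values on a 1e-6 grid: coarse enough that affine maps cannot create
    # new ties by floating-point absorption, fine enough to carry ties
    data=st.lists(
        st.integers(-10**9, 10**9).map(lambda k: k * 1e-6),
        min_size=13,
        max_size=60,
    ),
    scale=st.floats(0.1, 10),
    offset=st.floats(-100, 100),
)
def test_pe_invariant_under_monotone_transforms(data, scale, offset):
    """Ordinal patterns see only order: PE(f(x)) == PE(x) exactly for
    strictly increasing f."""
    x = np.asarray(data)
    cfg = OrdinalConfig(4, 3)
    base = permutation_entropy(TimeSeries(x, 1.0), cfg)
    affine = permutation_entropy(TimeSeries(scale * x + offset, 1.0), cfg)
    assert affine == base
    squashed = permutation_entropy(TimeSeries(np.tanh(x / 2e3), 1.0), cfg)
    assert squashed == base


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    data=st.lists(st.floats(-100, 100, allow_nan=False), min_size=9, max_size=80),
    D=st.integers(2, 4),
)
def test_pe_range(data, D):
    x = np.asarray(data)
    if x.size < (D - 1) * 2 + 1:
        return
    pe = permutation_entropy(TimeSeries(x, 1.0), OrdinalConfig(D, 2))
    assert 0.0 <= pe <= np.log(math.factorial(D)) + 1e-12


def test_pe_time_reversal_d2_without_ties(rng):
    """For D=2 the up/down counts swap under reversal: PE is unchanged."""
    x = rng.standard_normal(500)
    cfg = OrdinalConfig(2, 1)
    fwd = permutation_entropy(TimeSeries(x, 1.0), cfg)
    rev = permutation_entropy(TimeSeries(x[::-1].copy(), 1.0), cfg)
    assert fwd == pytest.approx(rev, abs=1e-12)


def test_pe_curve_sine_minimum_at_period(sine20):
    """An exactly periodic signal has all-tied windows at tau = period,
    collapsing the pattern distribution: the PE curve's global minimum."""
    curve = pe_curve(sine20, D=5, tau_max=40)
    assert curve.argmin_tau() == 20
    assert curve.pe[19] == 0.0


def test_pe_curve_constant_and_noise(rng):
    flat = pe_curve(TimeSeries(np.ones(500), 1.0), D=3, tau_max=20)
    assert np.all(flat.pe == 0.0)
    assert flat.is_flat()
    noise = pe_curve(TimeSeries(rng.standard_normal(60_000), 1.0), D=3, tau_max=20)
    assert np.all(np.abs(noise.pe - np.log(6)) < 0.02)


def test_pe_curve_infeasible_tau_max_names_limit():
    ts = TimeSeries(np.arange(41.0), fs=1.0)
    with pytest.raises(ValueError, match="maximum feasible tau is 10"):
        pe_curve(ts, D=5, tau_max=11)
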