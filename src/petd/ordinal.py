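"""Ordinal (Bandt–Pompe) symbolization and permutation entropy.

A length-``D`` window of a signal, sampled every ``tau`` points, is reduced
to the permutation that sorts it in ascending order (its *ordinal pattern*).
Permutation entropy (PE) is the Shannon entropy, in nats, of the frequency
distribution of these patterns over all windows of the series.  Computed as
a function of the embedding delay ``tau``, PE dips when ``tau`` matches a
dominant timescale of the signal: the PE-vs-tau curve produced here is the
raw material for the PE-TD timescale estimator in :mod:`petd.timescales`.

Conventions (fixed, so distributions are comparable across runs):

* Ties are broken by temporal order — the earlier sample gets the lower
  rank ("stable" ranking).  A constant window therefore always maps to the
  identity pattern.
* Patterns are indexed by the lexicographic rank of the argsort tuple
  (Lehmer code), a bijection onto ``0 .. D!-1``.
* PE uses the natural logarithm and is *not* normalized by ``ln D!``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "OrdinalConfig",
    "PatternDistribution",
    "PECurve",
    "ordinal_pattern",
    "pattern_to_index",
    "index_to_pattern",
    "symbolize",
    "pattern_distribution",
    "permutation_entropy",
    "pe_curve",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like
        Samples, arbitrary units (mV for membrane traces, a.u. otherwise).
        Must be finite and non-empty.
    fs : float
        Sampling rate in Hz, strictly positive.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("TimeSeries requires a non-empty 1-D array of samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("TimeSeries values must all be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Duration in seconds (n / fs)."""
        return self.n / self.fs


@dataclass(frozen=True)
class OrdinalConfig:
    """Embedding dimension ``D`` (window length) and delay ``tau`` (spacing)."""

    D: int = 5
    tau: int = 1

    def __post_init__(self) -> None:
        if int(self.D) != self.D or self.D < 2:
            raise ValueError(f"embedding dimension D must be an integer >= 2, got {self.D}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"embedding delay tau must be an integer >= 1, got {self.tau}")
        object.__setattr__(self, "D", int(self.D))
        object.__setattr__(self, "tau", int(self.tau))

    def min_length(self) -> int:
        """Minimum series length yielding at least one symbol."""
        return (self.D - 1) * self.tau + 1


@dataclass(frozen=True)
class PatternDistribution:
    """Counts and relative frequencies over all ``D!`` ordinal patterns."""

    counts: np.ndarray
    probs: np.ndarray
    n_symbols: int
    D: int


@dataclass(frozen=True)
class PECurve:
    """Permutation entropy as a function of the embedding delay.

    ``pe[i]`` is the PE (nats) at delay ``taus[i]``; delays run 1..tau_max.
    """

    taus: np.ndarray
    pe: np.ndarray
    D: int
    fs: float

    def argmin_tau(self) -> int:
        """Smallest delay attaining the global minimum of the curve."""
        return int(self.taus[int(np.argmin(self.pe))])

    def is_flat(self, atol: float = 1e-12) -> bool:
        return bool(np.ptp(self.pe) <= atol)


# -- pattern arithmetic -------------------------------------------------------

_MAX_TABLE_D = 7  # above this, D**D lookup tables get unreasonable


def ordinal_pattern(window: Sequence[float]) -> tuple[int, ...]:
    """Ordinal pattern of one window: the stable argsort permutation.

    ``window[pattern[0]] <= window[pattern[1]] <= ...`` with ties resolved
    in favor of the earlier index, e.g. ``[1.2, 3.4, 2.1] -> (0, 2, 1)`` and
    ``[5, 5, 5] -> (0, 1, 2)``.
    """
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("window must be 1-D with at least two values")
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    return tuple(int(i) for i in np.argsort(w, kind="stable"))


def pattern_to_index(pattern: Sequence[int]) -> int:
    """Lexicographic rank (Lehmer code) of a permutation among all ``D!``."""
    D = len(pattern)
    if sorted(pattern) != list(range(D)):
        raise ValueError(f"{pattern!r} is not a permutation of 0..{D - 1}")
    idx = 0
    for k in range(D):
        smaller_later = sum(1 for j in range(k + 1, D) if pattern[j] < pattern[k])
        idx += smaller_later * math.factorial(D - 1 - k)
    return idx


def index_to_pattern(index: int, D: int) -> tuple[int, ...]:
    """Inverse of :func:`pattern_to_index`."""
    if not 0 <= index < math.factorial(D):
        raise ValueError(f"index {index} out of range for D={D}")
    remaining = list(range(D))
    out = []
    for k in range(D):
        f = math.factorial(D - 1 - k)
        q, index = divmod(index, f)
        out.append(remaining.pop(q))
    return tuple(out)


# Lookup tables mapping a base-D encoding of the rank vector of a window to
# the lexicographic index of its ordinal pattern; built lazily per D.
_RANKCODE_TABLES: dict[int, np.ndarray] = {}


def _rankcode_table(D: int) -> np.ndarray:
    table = _RANKCODE_TABLES.get(D)
    if table is None:
        table = np.zeros(D**D, dtype=np.int64)
        import itertools

        for ranks in itertools.permutations(range(D)):
            # a window whose values equal its ranks reproduces those ranks
            code = sum(r * D**j for j, r in enumerate(ranks))
            table[code] = pattern_to_index(ordinal_pattern(np.asarray(ranks, float)))
        _RANKCODE_TABLES[D] = table
    return table


def _check_feasible(N: int, cfg: OrdinalConfig) -> int:
    n_sym = N - (cfg.D - 1) * cfg.tau
    if n_sym < 1:
        raise ValueError(
            f"series of length {N} too short for D={cfg.D}, tau={cfg.tau}: "
            f"need N >= {cfg.min_length()}"
        )
    return n_sym


def _rank_vectors(x: np.ndarray, D: int, tau: int, n_sym: int) -> list[np.ndarray]:
    """Stable ranks of each window element, via D(D-1)/2 vector comparisons.

    rank[j] = #{k < j : x_k <= x_j} + #{k > j : x_k < x_j}; with a total
    order, (x_k <= x_j) == ~(x_j < x_k), so only strict comparisons of
    later-vs-earlier elements are needed.
    """
    cols = [x[k * tau : k * tau + n_sym] for k in range(D)]
    ranks = [np.zeros(n_sym, dtype=np.int64) for _ in range(D)]
    for u in range(D):
        for v in range(u + 1, D):
            late_lt_early = cols[v] < cols[u]
            ranks[v] += ~late_lt_early  # x_u <= x_v
            ranks[u] += late_lt_early
    return ranks


def _encode_symbols(x: np.ndarray, D: int, tau: int, n_sym: int) -> np.ndarray:
    """Pattern index per window (vectorized; bit-exact vs. the naive path)."""
    ranks = _rank_vectors(x, D, tau, n_sym)
    if D <= _MAX_TABLE_D:
        code = ranks[0].copy()
        for j in range(1, D):
            code += ranks[j] * D**j
        return _rankcode_table(D)[code]
    # large D: invert the rank permutation, then Lehmer-encode directly
    pat = np.empty((D, n_sym), dtype=np.int64)
    ar = np.arange(n_sym)
    for j in range(D):
        pat[ranks[j], ar] = j
    idx = np.zeros(n_sym, dtype=np.int64)
    for k in range(D - 1):
        c = np.zeros(n_sym, dtype=np.int64)
        for j in range(k + 1, D):
            c += pat[j] < pat[k]
        idx += c * math.factorial(D - 1 - k)
    return idx


def symbolize(series: TimeSeries, cfg: OrdinalConfig) -> np.ndarray:
    """Map a series to its sequence of ordinal-pattern indices.

    Window ``i`` is ``(x[i], x[i+tau], ..., x[i+(D-1)tau])``; the result has
    ``N - (D-1)*tau`` entries, each in ``0 .. D!-1`` under the lexicographic
    bijection of :func:`pattern_to_index`.
    """
    n_sym = _check_feasible(series.n, cfg)
    return _encode_symbols(series.values, cfg.D, cfg.tau, n_sym)


def pattern_distribution(symbols: np.ndarray, D: int) -> PatternDistribution:
    """Empirical distribution over all ``D!`` patterns (zero counts kept)."""
    s = np.asarray(symbols)
    if s.size == 0:
        raise ValueError("cannot build a distribution from an empty symbol sequence")
    n_patterns = math.factorial(D)
    if s.min() < 0 or s.max() >= n_patterns:
        raise ValueError(f"symbol indices out of range 0..{n_patterns - 1}")
    counts = np.bincount(s, minlength=n_patterns)
    return PatternDistribution(
        counts=counts,
        probs=counts / s.size,
        n_symbols=int(s.size),
        D=D,
    )


def _entropy_nats(probs: np.ndarray) -> float:
    p = probs[probs > 0]
    return float(max(-np.sum(p * np.log(p)), 0.0))


def permutation_entropy(series: TimeSeries, cfg: OrdinalConfig) -> float:
    """PE = −Σ p_i ln p_i over the ordinal-pattern distribution, in nats.

    Lies in ``[0, ln D!]``; zero iff a single pattern occurs (monotone or
    constant series), maximal for equidistributed patterns.
    """
    dist = pattern_distribution(symbolize(series, cfg), cfg.D)
    return _entropy_nats(dist.probs)


def pe_curve(series: TimeSeries, D: int = 5, tau_max: int = 100) -> PECurve:
    """Permutation entropy at every delay ``tau = 1 .. tau_max``.

    Parameters
    ----------
    series : TimeSeries
    D : int
        Embedding dimension (default 5).
    tau_max : int
        Largest delay scanned (default 100).  The series must satisfy
        ``N >= (D-1)*tau_max + 1``.
    """
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1")
    N = series.n
    feasible = (N - 1) // (D - 1)
    if tau_max > feasible:
        raise ValueError(
            f"tau_max={tau_max} infeasible for series of length {N} at D={D}; "
            f"maximum feasible tau is {feasible}"
        )
    x = series.values
    nfact = math.factorial(D)
    pe = np.empty(tau_max, dtype=np.float64)
    for tau in range(1, tau_max + 1):
        n_sym = N - (D - 1) * tau
        sym = _encode_symbols(x, D, tau, n_sym)
        counts = np.bincount(sym, minlength=nfact)
        pe[tau - 1] = _entropy_nats(counts / n_sym)
    return PECurve(taus=np.arange(1, tau_max + 1), pe=pe, D=D, fs=series.fs)
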