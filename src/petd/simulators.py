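"""Ground-truth signal generators for validating timescale estimators.

Two model systems with known intrinsic timescales:

* a leaky integrate-and-fire (IAF) neuron, whose tonic inter-spike interval
  is the ground-truth timescale of its membrane-potential trace, plus a
  segment-concatenation protocol that manufactures controlled
  nonstationarity; and
* the Mackey–Glass delay oscillator, whose feedback delay ``tau_s`` sets the
  timescale of the generated series.

All stochastic pieces are driven by :class:`numpy.random.Generator` streams
and are bit-reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ordinal import TimeSeries

__all__ = [
    "IAFParams",
    "IAFInputSpec",
    "SpikeTrain",
    "MGParams",
    "DivergenceError",
    "simulate_iaf",
    "make_nonstationary",
    "mean_isi",
    "simulate_mackey_glass",
]


@dataclass(frozen=True)
class IAFParams:
    """Leaky integrate-and-fire parameters.

    Defaults describe a neuron with resting potential −70 mV, reset −75 mV,
    threshold −50 mV, membrane resistance 10 MΩ and decay constant 10 ms,
    integrated at 10 kHz.  With a constant drive I (nA), the membrane relaxes
    toward ``V_inf = V_rest + R*I`` (mV); tonic firing requires
    ``V_inf > V_th``, i.e. I above the 2 nA rheobase.
    """

    v_rest: float = -70.0  # mV
    v_reset: float = -75.0  # mV
    v_th: float = -50.0  # mV
    fs: float = 10_000.0  # Hz
    r_m: float = 10.0  # MΩ  (so r_m * I[nA] is in mV)
    tau_m: float = 10.0  # ms

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be > 0")
        if self.tau_m <= 0:
            raise ValueError("membrane time constant tau_m must be > 0")
        if not (self.v_reset <= self.v_rest < self.v_th):
            raise ValueError("require v_reset <= v_rest < v_th")


@dataclass(frozen=True)
class IAFInputSpec:
    """Input drive: a per-segment DC level plus per-sample white noise.

    The DC component (nA) is drawn once per simulated segment from
    ``Normal(dc_mean, dc_sd)``; white noise ``Normal(noise_mean, noise_var)``
    is added independently at every sample.  Redrawing the DC level segment
    by segment is what makes a concatenation of segments nonstationary: the
    firing rate tracks the drive.
    """

    dc_mean: float = 4.0  # nA
    dc_sd: float = 1.0  # nA
    noise_mean: float = 0.0
    noise_var: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")
        if self.dc_sd < 0:
            raise ValueError("dc_sd must be >= 0")


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times in seconds, strictly increasing."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("spike times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


def simulate_iaf(
    params: IAFParams,
    input_spec: IAFInputSpec,
    n_samples: int,
    rng: np.random.Generator | None = None,
) -> tuple[TimeSeries, SpikeTrain]:
    """Euler-integrate a leaky IAF neuron; return (membrane trace, spikes).

    The membrane follows ``tau_m dV/dt = -(V - V_rest) + R*I(t)`` at step
    ``1/fs``; whenever V reaches threshold a spike is recorded and V resets.
    ``I(t) = I_dc + xi(t)`` with I_dc drawn once from the input spec and
    xi(t) iid white noise.  The recorded trace holds the post-reset value at
    spike samples (no artificial spike peak is painted in).

    Passing ``rng`` overrides ``input_spec.seed``; either way the output is
    bit-reproducible.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng(input_spec.seed)
    dt_ms = 1000.0 / params.fs
    alpha = dt_ms / params.tau_m
    i_dc = input_spec.dc_mean
    if input_spec.dc_sd > 0:
        i_dc += input_spec.dc_sd * rng.standard_normal()
    if input_spec.noise_var > 0:
        drive = params.r_m * (
            i_dc
            + input_spec.noise_mean
            + np.sqrt(input_spec.noise_var) * rng.standard_normal(n_samples)
        )
    else:
        drive = np.full(n_samples, params.r_m * (i_dc + input_spec.noise_mean))

    v = params.v_rest
    v_rest, v_th, v_reset = params.v_rest, params.v_th, params.v_reset
    trace = np.empty(n_samples)
    trace[0] = v
    spike_idx = []
    for t in range(1, n_samples):
        v += alpha * (v_rest - v + drive[t])
        if v >= v_th:
            spike_idx.append(t)
            v = v_reset
        trace[t] = v
    times = np.asarray(spike_idx, dtype=np.float64) / params.fs
    return TimeSeries(trace, params.fs), SpikeTrain(times)


def make_nonstationary(segments: Sequence[TimeSeries], target_len: int) -> TimeSeries:
    """Truncate and concatenate stationary segments into one signal.

    Each of the ``k`` segments contributes its first ``target_len // k``
    samples (the remainder goes to the last segment), so the output length is
    exactly ``target_len`` — the same length as one original segment in the
    standard protocol, making stationary and nonstationary signals directly
    comparable.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to build a nonstationary signal")
    fs = segments[0].fs
    if any(s.fs != fs for s in segments):
        raise ValueError("all segments must share the same sampling rate")
    k = len(segments)
    chunk = target_len // k
    lens = [chunk] * k
    lens[-1] += target_len - chunk * k
    if chunk < 1:
        raise ValueError(f"target_len={target_len} too small for {k} segments")
    for seg, ln in zip(segments, lens):
        if seg.n < ln:
            raise ValueError(
                f"segment of {seg.n} samples shorter than its {ln}-sample share"
            )
    values = np.concatenate([seg.values[:ln] for seg, ln in zip(segments, lens)])
    return TimeSeries(values, fs)


def mean_isi(spikes: SpikeTrain) -> float:
    """Mean inter-spike interval in seconds (needs at least two spikes)."""
    if spikes.n_spikes < 2:
        raise ValueError(
            f"mean ISI undefined with {spikes.n_spikes} spike(s); need >= 2"
        )
    return float(np.mean(np.diff(spikes.times)))


def iaf_isi_tonic(params: IAFParams, i_dc: float) -> float:
    """Closed-form tonic ISI (s) for constant drive, ignoring discretization.

    ``ISI = tau_m * ln((V_inf - V_reset) / (V_inf - V_th))`` with
    ``V_inf = V_rest + R * I``; raises if the drive is subthreshold.
    """
    v_inf = params.v_rest + params.r_m * i_dc
    if v_inf <= params.v_th:
        raise ValueError(f"drive {i_dc} nA is subthreshold (V_inf={v_inf} mV)")
    return (
        params.tau_m
        / 1000.0
        * float(np.log((v_inf - params.v_reset) / (v_inf - params.v_th)))
    )


# -- Mackey–Glass -------------------------------------------------------------


class DivergenceError(RuntimeError):
    """Euler integration of the delay equation blew up."""


@dataclass(frozen=True)
class MGParams:
    """Mackey–Glass oscillator ``dx/dt = -x + a*x_d / (1 + x_d^c)``.

    ``x_d = x(t - tau_s*dt)``: the delay ``tau_s`` is expressed in
    integration steps of ``dt`` (default 1 ms), the natural unit when errors
    of delay estimators are reported in steps.  ``a`` is the feedback
    strength and ``c`` the degree of nonlinearity; the nontrivial fixed
    point ``x* = (a - 1)^(1/c)`` exists for a > 1 and loses stability to
    oscillations as the delay and nonlinearity grow.
    """

    a: float = 4.0
    c: float = 16.0
    tau_s: int = 160
    dt: float = 0.001
    duration: float = 5.0
    history: float = 0.5

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("feedback strength a must be > 0")
        if self.c < 1:
            raise ValueError("nonlinearity degree c must be >= 1")
        if int(self.tau_s) != self.tau_s or self.tau_s < 1:
            raise ValueError("delay tau_s must be an integer >= 1 (in steps)")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")
        object.__setattr__(self, "tau_s", int(self.tau_s))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


_BLOWUP = 1e6


def simulate_mackey_glass(
    params: MGParams,
    discard_transient: bool = True,
) -> TimeSeries:
    """Euler-integrate the Mackey–Glass equation; fs is reported as 1/dt.

    The history buffer (one delay long) is initialized to the constant
    ``params.history``.  With ``discard_transient`` the first
    ``min(10*tau_s, n_steps//2)`` steps are dropped so estimators see the
    attractor rather than the approach to it.  ``|x| > 1e6`` raises
    :class:`DivergenceError`.
    """
    n = params.n_steps
    tau = params.tau_s
    if n < tau:
        raise ValueError(
            f"duration of {n} steps shorter than the delay tau_s={tau}"
        )
    a, c, dt = params.a, params.c, params.dt
    buf = np.empty(tau + n)
    buf[:tau] = params.history
    for i in range(tau, tau + n):
        xd = buf[i - tau]
        x = buf[i - 1]
        x_new = x + dt * (-x + a * xd / (1.0 + xd**c))
        if not np.isfinite(x_new) or abs(x_new) > _BLOWUP:
            raise DivergenceError(
                f"Mackey–Glass integration diverged at step {i - tau} "
                f"(a={a}, c={c}, tau_s={tau})"
            )
        buf[i] = x_new
    x_out = buf[tau:]
    if discard_transient:
        skip = min(10 * tau, n // 2)
        x_out = x_out[skip:]
    return TimeSeries(x_out, fs=1.0 / dt)
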