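# Methods

## Ordinal symbolization and PE-TD

A window of `D` samples spaced `τ` apart is mapped to the permutation that
sorts it ascending. Equal values are ranked by temporal order (the earlier
sample gets the lower rank), so constant windows deterministically map to
the identity pattern; this matters for discretized or exactly periodic
signals, where ties are the rule rather than the exception. Patterns are
indexed by the lexicographic rank of the argsort tuple (Lehmer code), a
fixed bijection onto `0 … D!−1`, so pattern distributions are comparable
across runs and implementations. Permutation entropy is the Shannon entropy
of the pattern frequencies in nats, unnormalized (PE-TD only needs the
argmin, which normalization by `ln D!` cannot move).

PE-TD scans `τ = 1 … τ_max` and returns the smallest delay attaining the
global minimum of the curve. Defaults are `D = 5` (a standard compromise:
`5! = 120` patterns resolve structure well while 40,000-sample traces still
populate the distribution) and `τ_max = 100` samples for 250 Hz EEG-like
data; the integrate-and-fire experiments use `τ_max = 200` (20 ms at
10 kHz, comfortably above twice the ~81-sample tonic inter-spike interval of
the default neuron). A flat curve (constant or strictly monotone input) is
reported with a `degenerate` flag and a warning rather than an error; the
smallest-τ tie-break then decides the value.

Timescales are converted to seconds by *dividing* the delay by the sampling
rate. (Descriptions of this estimator sometimes say "multiplied by the
sampling rate"; dimensional analysis — 50 samples at 250 Hz must come out as
0.2 s — requires division.)

The vectorized symbolizer computes within-window ranks from the
`D(D−1)/2` pairwise comparisons of delayed copies of the signal and looks
up the pattern index through a precomputed rank-code table (`D ≤ 7`;
beyond that it falls back to direct Lehmer encoding). A naive per-window
argsort + dictionary-counting implementation lives in the test suite and is
compared bit-exactly against the vectorized path.

## ACW-0

The autocorrelation function uses the biased (divide-by-`N`) autocovariance
normalized by `c₀`, computed via FFT (`statsmodels`). ACW-0 is the smallest
integer lag with `r(l) ≤ 0`; no sub-sample interpolation is attempted. On a
pure sinusoid of period `P` the biased estimator's `O(1/N)` boundary term
can push the crossing one sample past the ideal `P/4`; tests allow that one
sample. For long recordings ACW-0 is computed in sliding windows (20 s,
50 % overlap, ACF scanned to half the window length) and the window
estimates are averaged arithmetically, dropping an incomplete trailing
window; short traces (e.g. 5 s oscillator runs) use the whole-trace ACF.

## Integrate-and-fire neuron

Standard leaky integrate-and-fire, Euler-integrated at `fs = 10 kHz`:

    τ_m dV/dt = −(V − V_rest) + R·I(t),  spike & reset when V ≥ V_th

with `V_rest = −70 mV`, `V_reset = −75 mV`, `V_th = −50 mV`, `R = 10 MΩ`,
`τ_m = 10 ms`. Currents are in nA so `R·I` is in mV; the tonic ISI has the
closed form `τ_m ln((V∞−V_reset)/(V∞−V_th))`, `V∞ = V_rest + R·I`, with a
2 nA rheobase. The recorded trace holds the post-reset potential (no spike
peak is painted in); painting peaks was tried and does not change any
estimator's behavior materially.

### Input structure and the nonstationarity protocol

Each experiment iteration builds 8 stationary segments of 40,000 samples
(4 s). In the default `either` input mode, half the segments (balanced,
randomly ordered) receive a constant DC drive drawn once per segment from
`N(4, 1)` nA — tonic, noiseless spiking whose exact mean ISI is the ground
truth — and half receive pure zero-mean unit-variance white noise, which is
subthreshold and produces a quiescent fluctuating trace. The
segment-to-segment switching of drive regime (and of the DC level) is the
source of nonstationarity when segments are truncated to 5,000 samples each
and concatenated into one 4 s signal.

This either/or reading is a deliberate design choice. The alternative
(`combined` mode, every segment DC + white noise, kept available for
sensitivity analysis) makes the membrane ramp between spikes smooth at
lag 1 while scrambling the cross-cycle sample alignment: the PE curve's
global minimum then sits at τ = 1 for every noise amplitude we examined,
and the estimator never sees the ISI. Only noiseless tonic segments are
exactly periodic under Euler integration, which is what lets the ordinal
ties collapse the pattern distribution at τ = ISI. Spiking segments are
redrawn when they have fewer than two spikes or a true ISI outside the
PE-TD search bracket (the DC distribution has an unbounded ISI tail near
rheobase; about 5 % of draws are redrawn): the experiment measures
estimator accuracy inside its bracket, not bracket selection.

Two RMSEs summarize the study: *stationary* — PE-TD vs true mean ISI,
pooled over all spiking segments of all iterations (a per-iteration-mean
variant is also reported); *nonstationary* — PE-TD of each concatenated
signal vs the mean PE-TD of its segments, over iterations. The default
replication count in the acceptance script and study-scale tests is 100
iterations, which makes the Monte-Carlo error on both RMSEs small relative
to the quantities themselves.

A caveat the experiments make explicit: truncating a spiking segment cuts
mid-cycle, so every chunk boundary of the concatenated signal carries a
phase jump. The concatenation of even *identical* segments is therefore
periodic with the chunk length, not stationary, and the concatenated
signal's PE minimum generally falls to the smooth-trace floor at small τ
rather than to one of the segment periods. The nonstationary RMSE measures
exactly this gap.

## Mackey–Glass delay oscillator

    dx/dt = −x + a·x(t−τ_s) / (1 + x(t−τ_s)^c)

Euler-integrated with `Δt = 0.001` for 5 s (5,000 steps); the delay `τ_s`
is expressed in integration steps (50–300 steps fit 16–100 delay periods in
a run; continuous-time delays of that magnitude would not). The history
buffer is the constant 0.5; the first `min(10 τ_s, n/2)` steps are
discarded so estimators see the attractor. The nontrivial fixed point
`x* = (a−1)^{1/c}` exists for `a > 1`; weak feedback decays to zero and is
flagged degenerate downstream. `|x| > 10⁶` raises a divergence error
(the flow is bounded for sane `Δt`, so this guards against absurd step
sizes, not normal use).

The nonlinearity sweep holds the delay at 160 steps and scans
`c = 1 … 30`. The fixed feedback strength is `a = 12`, chosen mid-range in
the oscillatory regime because it yields the canonical error profile for
ACW-0: wildly unstable estimates for weak nonlinearity, an exact optimum
(zero error) at `c = 16`, and slowly renewed drift beyond. Both the grid
and `a` are config-exposed and echoed in output metadata. Errors are
signed, `estimate − true delay`, in steps (seconds = steps × Δt).

### Known limitation: ordinal delay estimation needs sample-scale roughness

At `Δt = 0.001` the integrated trajectory moves ~0.1 % of its amplitude per
step. Five consecutive samples are then almost always monotone, the
identity pattern dominates at τ = 1, and the PE curve's global minimum sits
at the smallest delay for every `(a, c)` we scanned. PE-TD consequently
cannot recover the feedback delay from these traces — the delay signature
in ordinal statistics requires variability at the sampling scale
(broadband content, measurement noise, or coarser sampling), which is
present in real EEG and in the spiking-neuron traces but not in a smooth
ODE solution sampled at a fine step. In the sweep outputs PE-TD's error is
therefore a constant offset, and delay recovery on this system is carried
by ACW-0 (which exploits the oscillation period ≈ 4 τ_s of the
short-delay limit cycle). The corresponding study-scale tests assert the
observed behavior of both estimators and are the honest record of this
limitation.

## Group statistics

Channel maps hold one timescale (seconds) per channel; group maps are
channel-wise means over subjects (matching label sets enforced). Map
agreement uses Spearman's rank correlation by default (Pearson available —
both conventions exist in the INT literature). Two tests compare a
correlation between groups:

- **bootstrap** — channel indices resampled with replacement independently
  within each group, `r₁* − r₂*` recomputed per replicate; the replicate
  distribution is shifted to zero (centered at the observed difference) to
  serve as the null, and the two-sided p-value uses the add-one correction
  `(k+1)/(B+1)` with `B = 10,000` by default. Degenerate resamples
  (constant vectors) are redrawn and counted. Fully seeded; on Gaussian
  synthetic data at n = 200 the p-value agrees with the Fisher-z test
  within 0.05 (asserted in the suite).
- **Fisher z** — `z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3))`,
  two-sided normal p.

Subject-level group differences use the two-sided Wilcoxon rank-sum test on
per-subject channel means (normal approximation, average ranks for ties;
fully tied data warn).

## Synthetic multichannel generator

The generator stands in for resting-state hd-EEG, which cannot be shipped.
Each channel mixes three components chosen to reproduce the conditions
under which ordinal delay estimation works on real EEG:

1. a *harmonic-rich* (nonsinusoidal) oscillation whose period increases
   linearly across channels (default 0.21–0.36 s at 250 Hz, emulating the
   posterior-to-anterior INT gradient) — phase-locked harmonics provide
   fast deterministic structure, keeping PE high at small delays while
   values still repeat exactly cycle to cycle;
2. a large slow quasi-periodic drift (~3.5 and ~5.3 s components) that
   orders same-phase samples across cycles, carving the PE dip at the
   period;
3. a little white measurement noise (amplitude 0.04 of the oscillation).

The default period range starts above half the default PE-TD search range
so the octave-ambiguous dip at twice the period falls outside the scan. In
the stationary *conscious-like* regime both estimators are monotone in the
injected period and their maps correlate near 1. The *uws-like* regime
gives each channel a gradient-free distractor rhythm to which each 5 s
segment switches with probability 1/4: PE-TD (winner-take-all global
minimum) and ACW-0 (window-averaged) then stop tracking the same effective
period and the map correlation drops to a moderate value — the generator's
analogue of the reduced map agreement seen when consciousness is lost.

What passing these tests shows — and what it does not: the generator
demonstrates that the pipeline recovers a known gradient and that the two
estimators dissociate under piecewise-stationary rhythm switching. It does
not emulate 1/f spectra, volume conduction, artifacts, or subject
heterogeneity, so numerical correlation values on real EEG will differ;
only the direction of the regime contrast is the claim.

## Numerical conventions

- All randomness flows through `numpy.random.Generator`; experiment-level
  functions take one seed and derive everything from it, so every result is
  a pure function of (config, seed).
- Flat-curve detection uses a 1e−12 peak-to-peak threshold; `0 · ln 0 = 0`;
  PE is clipped at 0 against −0.0.
- Argmin ties resolve to the smallest delay; ACF zero crossing is the first
  lag ≤ 0; incomplete trailing ACW windows are dropped.
- Series too short for a configuration raise errors naming the feasible
  limit rather than returning NaN.
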