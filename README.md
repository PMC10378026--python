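# petd — intrinsic timescales via permutation entropy

Spontaneous neural activity stays correlated with itself over a
characteristic temporal window — its *intrinsic neural timescale* (INT).
The standard way to measure it is the autocorrelation window at zero
(**ACW-0**): the first lag at which the signal's autocorrelation function
crosses zero. This package implements an information-theoretic alternative,
**PE-TD** (permutation entropy–time delay): compute the permutation entropy

```
PE(τ) = − Σ_{i=1}^{D!} p_i ln p_i
```

of the distribution of ordinal (rank-order) patterns of `D` points spaced
`τ` samples apart, scan `τ = 1 … τ_max`, and take the delay at which PE
attains its global minimum. When `τ` matches the signal's dominant
timescale, windows sample equivalent phases of the underlying process, the
pattern distribution collapses, and the entropy dips. The estimate is
reported both in samples and in seconds (`τ / fs`) and is exactly invariant
under any strictly monotone transform of the signal amplitude.

The package is aimed at researchers analyzing resting-state M/EEG or
simulated neural signals who want a nonstationarity-tolerant INT estimator
next to the ACW-0 benchmark. It ships:

- `petd.ordinal` — Bandt–Pompe symbolization, pattern distributions, PE,
  and the PE-vs-τ curve (vectorized; ties broken by temporal order);
- `petd.timescales` — the PE-TD and ACW-0 estimators (whole-trace and
  sliding-window, 20 s / 50 % overlap by default);
- `petd.simulators` — ground-truth generators: a leaky integrate-and-fire
  (IAF) neuron with a segment-concatenation nonstationarity protocol, and
  the Mackey–Glass delay oscillator;
- `petd.experiments` — the validation studies (nonstationarity robustness;
  parameter sweeps of the delay-estimation error);
- `petd.group_stats` — channel-wise timescale maps, Spearman/Pearson map
  correlations, a seeded bootstrap and Fisher-z test for correlation
  differences, rank-sum group comparison, and a synthetic multichannel
  generator with a built-in timescale gradient;
- `petd.io` / the `petd` CLI — CSV/TSV matrices with JSON sidecars,
  optional EDF reading via `mne`, and subcommands for every study.

## Worked example

```python
import numpy as np
from petd import (IAFParams, IAFInputSpec, simulate_iaf, mean_isi, pe_td,
                  acw0, simulate_mackey_glass, MGParams)

# a tonically firing neuron: the inter-spike interval is the ground truth
params = IAFParams()                       # -70/-75/-50 mV, 10 MΩ, 10 ms, 10 kHz
trace, spikes = simulate_iaf(params, IAFInputSpec(dc_sd=0.0, noise_var=0.0), 40_000)
print(f"true mean ISI:   {mean_isi(spikes) * 1000:.3f} ms")
est = pe_td(trace, D=5, tau_max=200)
print(f"PE-TD estimate:  {est.tau_samples:.0f} samples = {est.seconds * 1000:.3f} ms")

# a nonlinear delay oscillator: the feedback delay is the ground truth
mg = simulate_mackey_glass(MGParams(a=12, c=16, tau_s=160))
print(f"ACW-0 on the delay oscillator (true delay 160 steps): "
      f"{acw0(mg).tau_samples:.0f} steps")
```

prints

```
true mean ISI:   8.100 ms
PE-TD estimate:  81 samples = 8.100 ms
ACW-0 on the delay oscillator (true delay 160 steps): 160 steps
```

The PE-TD minimum lands on the neuron's inter-spike interval to the sample
(81 samples at 10 kHz = 8.1 ms, the closed-form tonic ISI
`τ_m ln((V∞−V_reset)/(V∞−V_th))`), and ACW-0 recovers the oscillator's
feedback delay exactly at the well-conditioned nonlinearity degree c = 16.

The same operations are available from the shell, e.g.

```sh
petd sim-mg -a 12 -c 16 --tau 160 --out mg.csv
petd pe-td --input mg.csv --fs 1000 --tau-max 320 --out petd.json
petd exp-nonstat --n-iter 100 --seed 1 --out nonstat.json
```

Every output JSON embeds the resolved configuration and seed.

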