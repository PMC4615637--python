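# granular-reservoir

Rate-network models of the cerebellar granular layer treated as a
reservoir: random recurrent inhibition between granule cells (directly, or
relayed through Golgi cells) expands a band-limited behavioral input into
a rich set of temporal signals, from which a sparse linear readout — an
artificial Purkinje cell — can synthesize exponential basis filters of
different time constants. The package is for computational neuroscientists
studying temporal processing in the granular layer: it simulates the
networks, constructs and scores the filters, estimates stability, and
reproduces the full experiment grid (noise, input/weight variability,
sparseness, push-pull removal, Golgi afferent excitation, mGluR2
inhibition, nucleocortical output feedback).

## Model

Granule cells are memoryless rate units with rectification; all dynamics
come from single-exponential synapses. One-population form:

    z_i(t) = [ I_i(t) − Σ_j A_ij w_ij Σ_{s≤t} e^{−(t−s)/τ_w} z_j(s−1) + n N_i(t) ]⁺

Two-population form adds Golgi cells q_i(t) relaying inhibition (τ_w),
driven by fast granule excitation (τ_u), slow mGluR2/GIRK inhibition
(τ_m), optional direct afferent excitation g·I_i(t), and optional output
feedback L(t). Inputs are push-pull coded: I_i(t) = [I0_i ± 0.1·I0_i·x(t)]⁺
with x(t) colored noise (0–20 Hz, std 1/2). Readouts minimize
(1/2T)‖y − Zβ‖² + α‖β‖₁ (LASSO, α = 1e−4); quality is the squared Pearson
correlation R² on held-out test input. The empirical Lyapunov exponent
λ = log2(d̄_late/d̄_early)/2 s from paired perturbed/unperturbed silent runs
locates the edge of chaos, where slow-filter construction is best.

## Worked example

```python
import numpy as np
from granular_reservoir import (
    NetworkParams, SignalProtocol, build_signal_protocol, expand_inputs,
    build_connectivity_onepop, simulate_one_population,
    estimate_lyapunov, target_response, fit_readout, goodness_of_fit,
)

params = NetworkParams(w=1.4, tau_w=50.0)       # near the edge of chaos
protocol = SignalProtocol()                      # 5 s noise + 5 s silence, twice, + pulse
signal = build_signal_protocol(protocol, seed=1)
inputs = expand_inputs(signal, params.n_granule, seed=1)
conn = build_connectivity_onepop(params, seed=1)
traces = simulate_one_population(params, conn, inputs, seed=1)

train = signal.indices("train_noise", "train_silence")
test = signal.indices("test_noise", "test_silence")
y = target_response(signal.x, tau_ms=500.0)
fit = fit_readout(traces.z[train], y[train])
r2 = goodness_of_fit(fit.predict(traces.z[test]), y[test])
print(f"zeros: {100*fit.frac_zero:.0f}%  mean|b|>0: {fit.mean_abs_nonzero:.1f}  R2: {r2:.2f}")

lam = estimate_lyapunov(params, n_networks=3, seed=1).lam
print(f"lambda: {lam:.2f} bits/s")
```

Output (seed 1):

```
zeros: 71%  mean|b|>0: 45.2  R2: 0.68
lambda: 0.08 bits/s
```

Read: at w = 1.4 the slow 500 ms filter is reconstructed from only ~29 %
of the granule cells (LASSO drives the rest to exactly zero — the silent
parallel-fiber synapses), with R² ≈ 0.68 on unseen input, and the network
sits essentially at the edge of chaos (λ within noise of zero; the
zero crossing of the replicate-mean exponent falls between w = 1.2
and 1.4).
In the strongly stable regime (w = 0.01) the same filter fails while fast
filters succeed; in the chaotic regime (w = 3, λ > 0) all reconstruction
degrades.

## Command line

```
granular-reservoir sweep --scenario control --wgrid 0.01:3:25 --replicates 10 --seed 7 --out sweep.csv
granular-reservoir report sweep.csv           # edge_w and per-filter optima
granular-reservoir lyapunov --scenario control --seed 7
granular-reservoir feedback --wgrid 0.0,0.02,0.1 --seed 7 --out fb.csv
```

Scenarios (`control`, `noise`, `input_variability`, `weight_variability`,
`sparse`, `no_pushpull`, `twopop_control`, `golgi_afferent`, `mglur2`,
`feedback`) map to the study's experiment conditions; YAML configs override
any parameter and every output ships with a JSON manifest for exact replay.

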