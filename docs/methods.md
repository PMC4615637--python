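# Methods

## The model

The package simulates rate-neuron models of the cerebellar granular layer
viewed as a reservoir: a fixed random recurrent network expands a scalar
behavioral input into a high-dimensional set of granule-cell signals, and a
linear readout (an artificial Purkinje cell) is fitted afterwards to test
which temporal filters those signals can synthesize. Neurons are memoryless
rate units — all temporal structure comes from single-exponential synaptic
kernels — and firing rates are rectified at zero. There are no membrane
time constants, spikes, or conduction delays beyond the one-step update.

**One population.** Granule cells inhibit each other directly:

    z_i(t) = [ I_i(t) − Σ_j A_ij w_ij Σ_{s=1..t} e^{−(t−s)/τ_w} z_j(s−1)
               + n N_i(t) ]⁺

with Bernoulli(a) adjacency A, weights w_ij = (2/Nz)(w + v_w w ξ)⁺ drawn
once per network, and i.i.d. Gaussian intrinsic noise N_i(t) of std 1/2
(so the additive noise stays below amplitude n 95% of the time). The
division by Nz keeps the expected total inhibitory drive per cell at
2·a·w·(kernel sum), independent of network size.

**Two populations.** Inhibition is relayed by Golgi cells:

    z_i(t) = [ I_i(t) − Σ_j W_ij w_ij (K_{τ_w} * q_j) + L_i(t) ]⁺
    q_i(t) = [ g·I_i(t) + Σ_j B_ij ( u_ij (K_{τ_u} * z_j)
               − m_ij (K_{τ_m} * z_j) ) + L_i(t) ]⁺

with exact convergences (c_w = 4 Golgi per granule cell, c_u = 100 granule
per Golgi cell) and weights normalized by the convergence, (2/c_w)(w ± v_w w)⁺
and (2/c_u)(u ± v_u u)⁺. The m-term is the slow (τ_m = 50 ms) inhibition of
Golgi cells by granule-cell glutamate through mGluR2-activated GIRK
channels; `p_mglur_zero` knocks it out cell-wise (a knocked-out Golgi cell
loses all its incoming m-weights). The excitatory weight mean obeys
u = 0.1/τ_u so that the total steady excitatory gain c_u·mean(u_ij)·τ_u is
0.2 regardless of the excitatory time constant. g scales direct mossy-fiber
excitation of Golgi cells (0 by default). L(t) is the optional
output-feedback injection (below).

All kernel sums are evaluated with the O(T) recursion
c(t) = e^{−dt/τ} c(t−1) + r(t−1), which is exactly the explicit double sum
(unit tests verify the equivalence to < 1e−10 relative error). Integration
is synchronous with dt = 1 ms; every update uses rates from step t−1. Rates
above 1e6 (or non-finite) abort the run with the offending step index; such
replicates are excluded from averages and counted, never silently clipped.

## Input signal

The scalar signal x(t) mimics head velocity: Gaussian white noise with all
Fourier components above 20 Hz *and the DC component* zeroed (a behavioral
velocity signal is zero-mean; the DC choice also matters dynamically — see
"Output feedback"), rescaled to std(x) = 1/2 exactly. The protocol is
5 s noise + 5 s silence for training, the same again with a fresh noise
realization for testing, and a final 2 s segment containing a 50 ms unit
pulse (impulse probe; never used for fitting — it tests linearity of the
constructed filters). Silence is included in the fit so the readout learns
to output zero for zero input.

Each cell receives I_i(t) = [I0_i + f_i·0.1·I0_i·x(t)]⁺ with baseline
I0_i ~ N(1, v_I) clipped at zero. With push-pull coding f_i = ±1 with equal
probability (ipsilateral- vs contralateral-preferring mossy fibers);
without it f_i = +1 for all cells, which makes every afferent channel carry
the same waveform and is the model's main handicap condition. In the
two-population model the Golgi afferent ensemble (I0, f) is an independent
draw from the same distributions.

## Readout construction and scoring

Targets are exponential filters y_j = x * F_j, F_j(t) = e^{−t/τ_j},
τ ∈ {10, 100, 500} ms, computed over the concatenated signal so filter
memory crosses segment boundaries. Coefficients minimize

    (1/2T)·‖y − Zβ‖² + α·‖β‖₁,      α = 1e−4,

by coordinate descent (scikit-learn Lasso; Gram precomputation, 20 000
iterations — the α = 1e−4 problem converges slowly and the remaining drift
in the zero-coefficient fraction is ~2 pp), with no intercept and no column
standardization: granule rates enter in raw units, as a summation of
parallel-fiber inputs would. Zero coefficients are literal zeros produced
by soft thresholding. The positive-LASSO variant (`nonneg=True`) restricts
to excitatory weights. Goodness of fit is the squared Pearson correlation
on the held-out test rows; it is scale- and sign-blind by construction.
Both noise+silence (headline) and noise-only test scores are recorded.
Replicate evaluation redraws connectivity, afferents and noise per
replicate while holding the signal realization fixed ("identical
properties, different random connections").

## Stability analysis

The empirical Lyapunov exponent pairs a silent run (x ≡ 0) with a run whose
input is perturbed only at the first step (x(0) = 1e−14, entering through
every cell's afferent mapping). Intrinsic noise uses common random numbers
across the pair so the estimator measures dynamics, not noise. The granule
rate separation d(t) = ‖z − z′‖₂ is averaged across replicate networks
first, then

    λ = log2( mean(d̄, 2.01–2.11 s) / mean(d̄, 0.01–0.11 s) ) / 2 s

in bits/s; only the sign is interpreted. Separations below 1e−300 count as
exact zeros; a zero late window gives λ = −∞, a zero early window leaves λ
undefined. The edge of chaos is the first λ ≥ 0 → λ < 0 drop when scanning
the weight grid from strong inhibition downward (midpoint of the bracketing
interval). With the default one-population parameters the edge falls
between w = 1.2 and 1.4 at τ_w = 50 ms.

## Output feedback and teacher forcing

To model the nucleocortical pathway, the learned τ = 500 ms readout is fed
back: L_i(t) = f·o_i·(−Σ β z(t−1)) into 20 % of granule and Golgi cells
(recipients drawn once per network), o_i = [1e−4 ± 1e−5]⁺, signs split
50/50 excitatory/inhibitory. The loop uses the previous step's rates,
consistent with the explicit integration scheme.

β is learned open loop by teacher forcing with noise: the injected teacher
is the **one-step-delayed** target, −y₃(t−1)·N(t). The delay matters: the
closed loop can only ever deliver the previous step's readout, and a
teacher aligned with the current target lets the regression learn a
driverless unit-gain copy of y₃ whose closed loop carries no input
innovation and merely drifts. With the delayed teacher the fit is forced to
learn the actual transition y₃(t) = e^{−dt/τ}·y₃(t−1) + x(t), taking the
innovation from the afferent channels.

N(t) is multiplicative Gaussian noise of mean 1. Its level sets the closed
loop's memory: regression on a noisy channel attenuates the learned loop
gain by 1/(1+σ²), so the default σ = √(e^{dt/τ₃} − 1) ≈ 0.045 places the
attenuated gain exactly at the fed-back filter's own per-step decay —
enough memory to carry the slow filter, on the stable side of unit gain.
Larger σ shortens the loop memory (σ = 0.5 reduces the gain to ≈ 0.8, a
5 ms memory, and the loop collapses); σ → 0 leaves the gain within fitting
error of the stability boundary. A per-cell noise variant
(`teacher_noise_per_cell`) is available but not the default.

Known limitation: at intermediate inhibition (w ≳ 0.05) the regression
distributes the loop gain over the τ_w = 50 ms Golgi echo channels, and
the stability margin of the learned loop (≈ 1 − gain ≈ 0.002) is smaller
than the echo perturbation, so the closed loop is marginally unstable
there and the joint (all-three-filters) construction quality peaks at very
low w, carried by the loop's single integrator basis signal. Closed-loop
divergence is reported as an unstable outcome with counts, never silently
averaged.

## Synthetic data and what passing tests show

All inputs are generated internally; the package emulates band-limited
behavioral drive and random granular-layer wiring, not any recorded
dataset. It does not model spiking, synaptic plasticity, mossy-fiber spike
statistics, or cell types beyond granule and Golgi cells, so passing tests
certify properties of the rate-model reservoir (regime structure, filter
constructibility, directional parameter effects), not quantitative
predictions for biological recordings.

## Problem sizes used in tests and the acceptance script

Default populations are Nz = 1000 (and Nq = 100); single-network sparsity
statistics are averaged over 10 seeds at full size. Sweep-style checks use
the package's own scaled-down settings: 5-point weight grids, 3–5 replicate
networks, and Nz = 300 (Nq = 30) for the directional comparisons, sizes at
which the mean-field drive — and hence the regime structure — is unchanged
(the normalization makes total drive independent of Nz) while replicate
noise grows modestly. Sparsity statistics average 7 seeds; the closed-loop
feedback sweep uses a 4-point grid with 2 replicates. Full 25-point grids
with 10 replicates reproduce the complete curves and are available through
the CLI (`sweep`, `feedback`).

## Numerical choices

- Brick-wall spectral filtering for the colored noise (exactly testable
  band limit); exact std rescaling.
- Weight matrices are dense float64; the dominant cost is one
  matrix-vector product per step (≈ 11 s for a 22 s, Nz = 1000 run).
- Lyapunov runs need float64 throughout: separations start near 1e−15.
- Degenerate inputs: zero-variance series score R² = 0 with a warning;
  an all-zero design returns the zero solution; v_I = 0 and a = 0 are
  valid degenerate ensembles.
- Determinism: every random component draws from a named sub-stream of the
  master seed (`_streams.py`), so any component can be varied or held fixed
  independently, and identical seeds give bit-identical runs.
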