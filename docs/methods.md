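# Methods

## Spiking neuron models

Both simulators run on a fixed time grid, dt = 0.1 ms, with spike times
emitted on the grid. Input spike times are floor-snapped to the grid;
several spikes landing in one step sum their weights.

**Izhikevich class.** The canonical two-variable form

    v' = 0.04 v² + 5 v + 140 − u + I,    u' = a (b v − u),

with a spike emitted at v ≥ V_th = 30 mV followed by the hard reset
v ← c, u ← u + d. Integration is forward Euler with the update order of
the original published code: incoming spike weights are added to v
instantaneously, v is advanced one full step (optionally in n substeps,
for reproducing historic 0.5 ms-substep behavior), then u is advanced
using the *updated* v. All quantities except time (ms) and v (mV) are
treated as unitless. Initial conditions v(0) ~ U(−70, 30) mV,
u(0) = b·v(0), seeded; an explicit initial state can be supplied instead.
The packaged table holds the 14 variants with standard equations and
distinct parameters (variants with duplicate parameter sets, non-standard
equations, or grid-instability at dt < 0.5 ms are not included). Each
variant carries its weight factor ξ — the smallest single-spike synaptic
weight that triggers spiking from rest. The tabulated ξ values are
coarse (the simulated thresholds agree with them to a few percent, e.g.
15.157 vs 15.1 for tonic spiking); condition-level weights are expressed
as fractions of ξ and multiplied out internally.

**AMAT class.** A leaky integrator (τ_m = 10 ms, C_m = 200 pF,
E_L = −70 mV) with exponential synaptic currents (τ_E = 1 ms,
τ_I = 3 ms), advanced by exact integration: per-step propagators for the
linear (I_E, I_I, V) subsystem, so subthreshold trajectories carry no
truncation error. The spike threshold is

    θ(t) = ω + Σ_j [α₁ e^{−(t−t_j)/τ₁} + α₂ e^{−(t−t_j)/τ₂}] + θ_V(t),

summing over past output spikes (ω = −65 mV, τ₁ = 10 ms, τ₂ = 200 ms).
θ_V is the voltage-driven "augmented" component; the source defining its
exact ODE was not available, so it is implemented as the first-order
linear state τ_V θ_V' = −θ_V + β (V − E_L) with τ_V = 5 ms, propagated
by exponential Euler with V frozen over the step. β = 0 degenerates
exactly to the plain two-timescale adaptive threshold (tested). A spike
is emitted when V ≥ θ outside the absolute refractory period
τ_ref = 2 ms; the membrane potential is *not* reset. This refractory
period imposes the 500 s⁻¹ output-rate ceiling that the acceptance
script reproduces. V(0) ~ U(−70, −65) mV.

**Background noise.** Three named regimes: none; balanced (μ = 0,
σ = 0.1 for Izhikevich, σ = 100 pA for AMAT); biased (μ = −0.1/−100 pA,
σ = 0.2/200 pA). For the Izhikevich class the noise is a piecewise-
constant current redrawn independently every step with the stated mean
and standard deviation — deliberately without 1/√dt scaling, so the
effective diffusion is tied to dt = 0.1 ms; the preset σ values assume
this convention. For the AMAT class the noise is delivered as excitatory
and inhibitory Poisson input with fixed weights w_E = 1 pA,
w_I = −4/3 pA through the synaptic filters; the rates (ν_E, ν_I) follow
from (μ, σ) by exactly inverting the linear mean/variance relations of
filtered shot noise (both relations are linear in the rates, so the
inversion is a 2×2 solve; μ = 0, σ = 100 pA gives ν_E = 4ν_I ≈ 8.6×10⁶
events/s, sampled as Poisson counts per bin).

**Population runs.** Measurement protocols simulate N independent
generator–neuron pairs in one compiled pass and pool per-bin output
counts; equilibration (default 1 s) precedes recording. The compiled
kernels draw all randomness from one seeded generator, so every run is
reproducible bit for bit; pure-Python re-implementations of both update
loops serve as test oracles (bit-identity for Izhikevich, ≤1e−6 mV for
AMAT subthreshold trajectories).

## Stimuli

Poisson generators use the grid dialect: one Bernoulli draw per bin with
p = a(t)·dt (an error is raised if p > 1 anywhere); an exact
time-rescaling alternative is provided for distributional cross-checks.
Sinusoidal profiles a(t) = a₀ + a₁ sin(2πft) enforce 0 ≤ a₁ ≤ a₀ (no
rectification). The stepped test stimulus is the piecewise-constant
schedule 100/200/40/150 s⁻¹ over 0–600/600–1000/1000–1200/1200–1500 ms.

The synthetic retinal-ganglion-cell generator emulates recordings
characterized by low baseline firing and fast transients: an
inhomogeneous Poisson rate equal to an 8 s⁻¹ baseline plus 12 Gaussian
bumps (σ = 15 ms) spread evenly over each 8 s sweep, with the bump
amplitude computed analytically so the expected grand-mean rate is
18.3 s⁻¹ for the default 96-train set (≈183 s⁻¹ at the bump peak).
Pairwise merging (sorted union; coincident spikes offset by 1 µs) yields
48 trains at twice the rate. Only these summary statistics of the real
recordings are matched: the generator has regular event times and
homogeneous bump shapes, no trial-to-trial rate correlations, no
refractoriness, and Poisson count statistics. Tests passing on this
surrogate therefore certify the pipeline mechanics (rate recovery,
scoring, merging), not fidelity to any particular biological data set.

## Response characterization

**Rate estimation** uses the fixed-kernel variant of kernel-bandwidth
optimization for spike rates: pooled spikes are binned at 0.05 ms, and a
single global Gaussian width w minimizes the unbiased cost
C(w) = Σ_{ij} k_{√2w}(t_i−t_j) − 2Σ_{i≠j} k_w(t_i−t_j), evaluated by FFT
smoothing over a logarithmic width grid (40 widths by default; a
brute-force pairwise evaluation is the test oracle). The rate estimate is
boundary-corrected by the in-window kernel mass. Estimates whose optimal
width exceeds 15 ms are flagged invalid — such smoothing would wash out
the transients being scored — and a width on the candidate-grid boundary
warns.

**Harmonics.** Responses to f-periodic stimulation (an integer number
≥ 2 of periods) are decomposed as r(t) = r₀ + Σ r_m cos(2πmft + φ_m) via
the FFT of the pooled PSTH. The significance criterion for harmonic m
compares r_m against r_crit = B + 2.34Σ (one-sided 99% z-test), where B
and Σ summarize the background amplitude spectrum near the harmonic. The
exact background convention of the companion method was not available;
here B is the plain mean and Σ the inverse-distance-weighted standard
deviation over non-harmonic bins within ±25% of f around the harmonic
(at least ±3.5 frequency bins), both configurable. With records of a few
tens of periods the false-positive rate of the first harmonic is ≈2%
(tested); with the minimum 2 periods the background window is small and
the criterion is conservative only on average.

**Activation functions** g(a₀) are measured on the grid a₀ = 0, 10, …,
1000 s⁻¹ (101 knots), 10 s per knot after 1 s equilibration by default
(≈3% standard error at 100 s⁻¹), and represented as a linear B-spline
through the knots with linear end-slope extrapolation. **Linearity** over
[α, β] is scored by L₁ = 1/(1+L̄₁), with L̄₁ the mean-square deviation
from the continuous least-squares line normalized by the squared line
value at the midpoint (trapezoid-rule moments on a dense grid; NaN when
the line vanishes at the midpoint). **Burst spikes** are those within
5 ms of a neighboring spike.

## LN model identification and prediction

**Transfer functions** are measured at 28 log-spaced frequencies,
1–1000 Hz, snapped to the grid (relative adjustment < 1e−4; the
endpoints are exact). Each point uses an integer number of periods — at
least 2 and at least 1 s — and 1024 trials by default. The complex
estimate is H₀(f) = i (r₁/a₁) e^{iφ₁}; the factor i converts the
cosine-convention response phase to phase relative to the sine stimulus,
so a linear system returns its true H(f) (verified against a surrogate
Poisson responder with a known filter, |H| recovered within 5%).
Conditions with no significant first harmonic anywhere and mean rate
< 1 s⁻¹ are flagged missing rather than fitted.

**Filter fits** minimize the summed squared modulus of the complex
residuals H̃ − H₀ over (γ₁, γ₂, f_c1, f_c2, Δ); the residual form is a
package choice (the amplitude-and-phase loss uses all measured
information). Corner frequencies are optimized in log space within
0.909–636.6 Hz (τ_c from 0.25 to 175 ms), the delay within 0–75 ms. The
global strategy is multi-start bounded L-BFGS-B — 60 starts by default,
corner frequencies log-uniform, delays drawn from a fixed ladder plus
log-uniform values, seeded and deterministic. Noiseless synthetic
targets are recovered to well below 1%. A pure lowpass (γ₂ = 0) is
fitted from 15 starts for comparison, and its solution seeds one
bandpass start, so by construction the bandpass loss never exceeds the
lowpass loss. Fits with f_c1 > f_c2 are returned in canonical order via
the exact reparameterization (f's swapped, γ₁ ← γ₁γ₂, γ₂ ← 1/γ₂).

**Prediction.** The deliverable model is r(t) = max(0, g((h∗a)(t))) with
the normalized kernel (∫h = 1; rectification only guards against
negative extrapolation of g):

    h(t) = Θ(t−Δ) [ e^{−(t−Δ)/τ₁}/τ₁ + γ₂ e^{−(t−Δ)/τ₂}/τ₂ ] / (1+γ₂).

Two routes are implemented and cross-checked. The convolution route
integrates h analytically over each bin (exact for piecewise-constant
input) and applies FFT convolution, warm-started at the fixed point of
the initial rate; the kernel is truncated when the remaining tail mass
falls below 1e−12, so Σh = 1 to ≈1e−12. The ODE route uses the linear
chain trick — u₁' = −u₁/τ₁ + a(t−Δ)c₁/τ₁, u₂' = −u₂/τ₂ + a(t−Δ)c₂/τ₂
with c₁ = 1/(1+γ₂), c₂ = γ₂/(1+γ₂), the delay as an input buffer — with
exact exponential-integrator steps, so the two routes agree to machine
precision (tested at ≤1e−4 s⁻¹ RMS, including γ₂ ≈ −1.002, near the
normalization singularity; |1+γ₂| ≤ 1e−12 raises).

The default working-point grid is a₀ ∈ {50, 100, 200, 400, 800} s⁻¹ ×
a₁/a₀ ∈ {0.25, 0.5, 0.75, 1} (20 combinations).

## Scoring, selection, generalization, grouping

**Eᵣ.** Predictions are compared with the KDE rate of the pooled spiking
response by Ēᵣ = ∫(r_rate−r_spike)²dt / ∫(r_spike−r̄)²dt (rectangle rule)
and Eᵣ = 1/(1+Ēᵣ). By default the comparison window excludes the first
max(3×KDE width, min(Δ+3τ₂, T/3)) ms and the last 3×KDE width, dropping
KDE edge bias and kernel warm-up; a full-window option exists. A
zero-variance response yields a flagged missing value.

**Stepped-Poisson test.** Per condition: 4096 independent neurons, the
stepped schedule, 5 seeds by default; seeds whose optimal KDE width
exceeds 15 ms are discarded and Eᵣ is averaged over the rest; all seeds
invalid (or no spikes) gives a missing record. The naturalistic-train
test drives one neuron per input train (frozen trains, noise varying by
seed) and scores identically, using the KDE of the input trains (or the
known generator rate) as LN input. Eᵣ_opt selects the best (a₀, a₁) per
condition.

**Generalizations.** M: one model per variant — per-parameter medians of
(γ₁, γ₂, f_c1, f_c2, Δ) over all conditions, and the activation
w·ḡ(a) with ḡ the spline through knot-wise means of the weight-scaled
data g(a)/w (activations scale roughly linearly in w). MN: the same per
noise regime. MNW: per condition, medians over working points only,
original activation. MNWS: per condition, the filter of the working
point with the best stepped-test Eᵣ. Medians preserve the f_c1 ≤ f_c2
order and bounds because they hold row-wise. The quality of a
generalization X is ρ_X = Eᵣ^X / Eᵣ^opt (may exceed 1 when pooling beats
an overshooting per-condition fit).

**Grouping.** k-means (k = 7, 100 initializations, seeded) on the
5-vector (γ₁, γ₂, log₁₀f_c1, log₁₀f_c2, Δ), z-scored per dimension — the
log/z-score preparation is a package choice. Each variant goes to its
plurality cluster (ties prefer larger clusters, then lower index, for
determinism); occupied clusters become model groups with per-parameter
medians over the member variants' fits.

## Problem sizes used in the shipped checks

The test suite runs a reduced sweep chosen to be representative rather
than exhaustive: variants A (tonic spiking), C (tonic bursting) and Q
(depolarizing after-potential) of each class; all three noise regimes;
two weights (300/700 pA for AMAT, 0.25/0.6·ξ for Izhikevich — mid and
upper-mid points of the full five-weight ladder); a 4-point working
grid (a₀ ∈ {100, 400} × a₁/a₀ ∈ {0.5, 1}); 48 trials per
transfer-function frequency with 0.5 s equilibration; 24/8 fit starts;
and a 512-neuron, 2-seed stepped test. Activation functions use a 20 s⁻¹
knot spacing at 4 s per knot. On these conditions the AMAT subset
reaches Eᵣ_opt ≥ 0.8 in a larger fraction of conditions than the matched
Izhikevich subset, with tonic spiking/bursting excellent and
depolarizing after-potential clearly worst — the same ordering the
full-scale sweep (scripts/full_sweep.py) addresses. Single-condition
results at these sizes carry a few-percent Eᵣ spread across seeds.

## Known limitations

- The augmented-threshold ODE is the package's reconstruction (first-
  order lowpass of β(V−E_L)); variants with large |β| may deviate from
  other implementations of the same model family.
- The background-spectrum convention behind the harmonic significance
  test is a package choice; with very short records (2 periods) the
  criterion is noisy.
- KDE boundary correction removes edge mass loss but not edge variance;
  score windows therefore exclude 3 kernel widths at each end by
  default.
- The Bernoulli-per-bin Poisson dialect slightly under-disperses at
  rates approaching 1/dt (p close to 1); rates above 10⁴ s⁻¹ on the
  0.1 ms grid are rejected.
- Izhikevich tabulated ξ values are treated as nominal; internally all
  weights are absolute and thresholds can be recomputed by bisection.
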