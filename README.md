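# lnrate

Linear–nonlinear (LN) firing-rate reduction of spiking neuron models.

Rate-based network models need a quantitative account of how a neuron's
output firing rate follows its spiking input. `lnrate` builds that account
for two widely used spiking model classes — the **Izhikevich** model
(two-variable quadratic dynamics with hard reset) and the **augmented
multi-adaptive-threshold (AMAT)** model (linear subthreshold dynamics,
adaptive threshold, no reset) — by

1. simulating their spike responses to stationary and sinusoidally
   modulated Poisson input under three background-noise regimes,
2. measuring the static activation function g(a₀) (stationary output rate
   vs input rate) and the empirical transfer function
   H₀(f) = (r₁(f)/a₁)·e^{iφ(f)} at 28 frequencies from 1–1000 Hz,
3. fitting the bandpass filter

       H̃(f) = γ₁ e^{−2πifΔ} [ 1/(1+if/f_c1) + γ₂/(1+if/f_c2) ],
       0.909 Hz ≤ f_c1 ≤ f_c2 ≤ 636.6 Hz,  0 ≤ Δ ≤ 75 ms,

4. predicting rates with the LN cascade r(t) = max(0, g((h∗a)(t))), where
   h is the normalized (∫h = 1) time-domain kernel of H̃ — either by
   convolution or via the equivalent two-variable ODE system (linear
   chain trick), and
5. scoring predictions against spiking responses with the normalized-MSE
   quality Eᵣ = 1/(1+Ēᵣ), selecting optimal working points, pooling fits
   into four generalization levels (M, MN, MNW, MNWS), and grouping model
   variants by k-means clustering of filter parameters.

Parameter presets for 14 Izhikevich and 18 AMAT firing-pattern variants
(tonic/phasic spiking and bursting, resonator, bistability, …) are
packaged, along with a synthetic generator that emulates retinal-ganglion-
cell recordings (96 trains of 8 s, low baseline with fast transients,
grand-mean rate 18.3 s⁻¹).

## Worked example

Fit LN models for the AMAT tonic-spiking variant under balanced noise and
score them on the stepped-Poisson test stimulus
(100/200/40/150 s⁻¹ over 1.5 s):

```python
import numpy as np
from lnrate import (ModelSpec, NeuronSystem, fit_ln_models,
                    measure_activation_function)
from lnrate.evaluate import stepped_poisson_test, select_optimal

spec = ModelSpec("amat", "A")
act = measure_activation_function(spec, "balanced", w=500.0,
                                  a0_grid=np.arange(0, 1001, 20.0),
                                  duration=4000.0, equilibration=500.0,
                                  seed=1)
system = NeuronSystem(spec, noise="balanced", w=500.0, equilibration=500.0)
models = fit_ln_models(system, act,
                       working_points=[(100, 50), (100, 100),
                                       (400, 200), (400, 400)],
                       n_trials=48, n_starts=24, seed=2)
records = stepped_poisson_test(spec, models, "balanced", 500.0,
                               n_neurons=512, n_seeds=2, seed=3)
best = select_optimal(records)
print(f"Er_opt = {best.Er:.3f} at (a0, a1) = ({best.a0:g}, {best.a1:g})")
```

This prints

```
Er_opt = 0.942 at (a0, a1) = (100, 50)
```

i.e. the best of the four fitted LN models reproduces the spiking
population's rate response to the novel stepped stimulus with fit quality
Eᵣ ≈ 0.94 (1 would be a perfect match, 1/2 an error as large as the
response variance).

The same steps are available from the shell via the `lnrate` console
script (`simulate`, `activation`, `transfer`, `fit`, `predict`,
`stepped-test`, `rgc-test`, `generalize`, `cluster`, `synth-rgc`), e.g.

```sh
lnrate synth-rgc --n 96 --t 8 --seed 1 --merge --out out/
lnrate stepped-test --model amat:A --noise balanced --w 500 --out out/
```

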