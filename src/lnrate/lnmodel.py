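"""Linear-nonlinear (LN) rate models: transfer-function estimation,
bandpass-filter fitting, and rate prediction.

The linear stage is the sum-of-lowpass bandpass filter

    H(f) = gamma1 exp(-2 pi i f Delta)
           * [ 1/(1 + i f/f_c1) + gamma2/(1 + i f/f_c2) ],

whose time-domain kernel is a delayed sum of two exponentials with time
constants tau_k = 1/(2 pi f_ck).  The LN rate model applies the
*normalized* kernel h (integral 1, obtained by dividing by gamma1
(1+gamma2)) to the input rate a(t) and passes the result through the
static activation function g:  r(t) = max(0, g((h*a)(t))).  The linear
gain gamma1 is absorbed by g and does not enter the prediction.

Both an FFT-convolution route and an equivalent two-variable ODE route
(linear chain trick, exact exponential integration per grid step) are
provided for the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, signal

from .characterize import ActivationFunction, harmonics_from_counts
from .neuron_models import ModelSpec, population_counts

__all__ = [
    "F_C_MIN",
    "F_C_MAX",
    "DELAY_MAX",
    "FREQUENCY_GRID",
    "WORKING_POINTS",
    "FilterParams",
    "FilterFitResult",
    "TransferFunctionEstimate",
    "LNModel",
    "NeuronSystem",
    "eval_filter",
    "measure_transfer_function",
    "fit_filter",
    "filter_kernel",
    "predict_convolution",
    "predict_ode",
    "fit_ln_models",
]

#: corner-frequency bounds, from 0.25 ms <= tau_c <= 175 ms
F_C_MIN = 1.0 / (2.0 * np.pi * 0.175)       # Hz  (~0.909)
F_C_MAX = 1.0 / (2.0 * np.pi * 0.25e-3)     # Hz  (~636.6)
DELAY_MAX = 75.0                            # ms

#: 28 stimulation frequencies, log-spaced over 1-1000 Hz
FREQUENCY_GRID = np.logspace(0.0, 3.0, 28)

#: default working-point grid: a0 x relative modulation depth
WORKING_POINTS = tuple((a0, frac * a0)
                       for a0 in (50.0, 100.0, 200.0, 400.0, 800.0)
                       for frac in (0.25, 0.5, 0.75, 1.0))

_GAMMA2_GUARD = 1e-12


@dataclass(frozen=True)
class FilterParams:
    """Bandpass-kernel parameters (gains, corner frequencies, delay)."""

    gamma1: float
    gamma2: float
    f_c1: float
    f_c2: float
    delay: float  # ms

    def __post_init__(self):
        tol = 1e-6
        if not (F_C_MIN - tol <= self.f_c1 <= self.f_c2 + tol
                and self.f_c2 <= F_C_MAX * (1 + 1e-9) + tol):
            raise ValueError(
                f"corner frequencies must satisfy {F_C_MIN:.3f} Hz <= f_c1 "
                f"<= f_c2 <= {F_C_MAX:.1f} Hz, got ({self.f_c1}, {self.f_c2})")
        if not -tol <= self.delay <= DELAY_MAX + tol:
            raise ValueError(f"delay must lie in [0, {DELAY_MAX}] ms")
        if abs(1.0 + self.gamma2) <= _GAMMA2_GUARD:
            raise ValueError("1 + gamma2 is numerically zero; the normalized "
                             "kernel is undefined")

    @property
    def tau_c1(self) -> float:
        """First filter time constant, ms."""
        return 1000.0 / (2.0 * np.pi * self.f_c1)

    @property
    def tau_c2(self) -> float:
        """Second filter time constant, ms."""
        return 1000.0 / (2.0 * np.pi * self.f_c2)

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma1, self.gamma2, self.f_c1, self.f_c2,
                         self.delay])


@dataclass
class TransferFunctionEstimate:
    """Empirical transfer function H0(f) = (r1(f)/a1) e^{i phi(f)}."""

    frequencies: np.ndarray
    H: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    r1_significant: np.ndarray
    r2_significant: np.ndarray
    r0: np.ndarray
    valid: bool
    metadata: dict = field(default_factory=dict)


@dataclass
class FilterFitResult:
    params: FilterParams
    loss: float
    lowpass_params: FilterParams
    lowpass_loss: float


@dataclass
class LNModel:
    """Deliverable rate model: activation g plus normalized kernel h."""

    activation: ActivationFunction
    filter: FilterParams
    metadata: dict = field(default_factory=dict)


def eval_filter(p: FilterParams, f) -> np.ndarray:
    """Complex filter gain at frequency f (Hz); H(0) = gamma1 (1+gamma2)."""
    f = np.asarray(f, dtype=float)
    phase = np.exp(-2j * np.pi * f * p.delay * 1e-3)
    out = p.gamma1 * phase * (1.0 / (1.0 + 1j * f / p.f_c1)
                              + p.gamma2 / (1.0 + 1j * f / p.f_c2))
    return out if out.ndim else complex(out)


class NeuronSystem:
    """A spiking model variant under one input condition.

    Bundles model variant, background-noise regime and synaptic weight and
    exposes the pooled population response to an arbitrary rate profile —
    the probe interface used for activation-function and transfer-function
    measurements.  Any object with the same ``run`` signature (e.g. a
    surrogate Poisson responder with a known linear filter) can stand in.
    """

    def __init__(self, spec: ModelSpec, noise="none", w: float = 1.0,
                 dt: float = 0.1, equilibration: float = 1000.0):
        self.spec = spec
        self.noise = noise
        self.w = w
        self.dt = dt
        self.equilibration = equilibration

    def run(self, rate_full: np.ndarray, n_trials: int, seed: int) -> np.ndarray:
        """Pooled per-bin counts for the recording window.

        ``rate_full`` covers equilibration + recording on the dt grid.
        """
        return population_counts(self.spec, rate_full, self.w,
                                 noise=self.noise, n=n_trials, dt=self.dt,
                                 equilibration=self.equilibration, seed=seed)

    def describe(self) -> dict:
        return {"model": str(self.spec), "noise": str(self.noise),
                "w": self.w}


def measure_transfer_function(system, a0: float, a1: float,
                              frequencies: Optional[np.ndarray] = None,
                              n_trials: int = 1024,
                              min_duration: float = 1000.0,
                              min_periods: int = 2,
                              seed: int = 0) -> TransferFunctionEstimate:
    """Empirical transfer function from sinusoidally modulated Poisson drive.

    For each stimulation frequency the system is driven with
    a(t) = a0 + a1 sin(2 pi f t) over an integer number of periods (at
    least ``min_periods`` and at least ``min_duration`` ms), the pooled
    response is decomposed into harmonics, and

        H0(f) = i (r1/a1) e^{i phi1}

    (the factor i converts the cosine-convention response phase to the
    phase relative to the sine stimulus).  Frequencies are snapped to the
    simulation grid (relative adjustment < 1e-4).  The estimate is flagged
    invalid when no frequency shows a significant first harmonic and the
    mean rate stays below 1 s^-1.
    """
    if not 0 <= a1 <= a0:
        raise ValueError("need 0 <= a1 <= a0")
    freqs = np.asarray(FREQUENCY_GRID if frequencies is None else frequencies,
                       dtype=float)
    dt = system.dt
    n_equil = int(round(system.equilibration / dt))
    H = np.empty(freqs.size, dtype=complex)
    r1 = np.empty(freqs.size)
    r2 = np.empty(freqs.size)
    s1 = np.zeros(freqs.size, dtype=bool)
    s2 = np.zeros(freqs.size, dtype=bool)
    r0 = np.empty(freqs.size)
    f_eff = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        n_per = max(min_periods, int(np.ceil(f * min_duration * 1e-3)))
        n_rec = int(round(n_per * 1000.0 / (f * dt)))
        fe = n_per * 1000.0 / (n_rec * dt)
        f_eff[i] = fe
        t_rec = (np.arange(n_equil + n_rec) - n_equil) * dt
        rate = a0 + a1 * np.sin(2e-3 * np.pi * fe * t_rec)
        counts = system.run(rate, n_trials, seed=(seed + 7919 * i) % (2**31 - 1))
        if counts.sum() == 0:
            H[i] = np.nan
            r1[i] = r2[i] = np.nan
            r0[i] = 0.0
            continue
        hs = harmonics_from_counts(counts, n_trials, dt, fe, M=2)
        r0[i] = hs.r0
        r1[i], r2[i] = hs.r[0], hs.r[1]
        s1[i], s2[i] = hs.significant[0], hs.significant[1]
        H[i] = 1j * (hs.r[0] / a1) * np.exp(1j * hs.phi[0])
    valid = bool(np.any(s1) or np.nanmean(np.where(np.isnan(r0), 0, r0)) >= 1.0)
    meta = dict(getattr(system, "describe", dict)() or {})
    meta.update({"a0": a0, "a1": a1, "n_trials": n_trials, "seed": seed})
    return TransferFunctionEstimate(frequencies=f_eff, H=H, r1=r1, r2=r2,
                                    r1_significant=s1, r2_significant=s2,
                                    r0=r0, valid=valid, metadata=meta)


def _filter_loss(x, f, H0, lowpass):
    if lowpass:
        g1, u1, d = x
        g2, u2 = 0.0, np.log10(F_C_MAX)
    else:
        g1, g2, u1, u2, d = x
    fc1 = 10.0 ** u1
    fc2 = 10.0 ** u2
    Ht = g1 * np.exp(-2j * np.pi * f * d * 1e-3) * (
        1.0 / (1.0 + 1j * f / fc1) + g2 / (1.0 + 1j * f / fc2))
    res = Ht - H0
    return float(np.sum(res.real ** 2 + res.imag ** 2))


_DELAY_LADDER = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 40.0, 75.0)


def fit_filter(tf: TransferFunctionEstimate, n_starts: int = 60,
               n_starts_lowpass: int = 15, seed: int = 0) -> FilterFitResult:
    """Fit the bandpass filter to an empirical transfer function.

    Minimizes the summed squared modulus of the complex residuals over
    (gamma1, gamma2, f_c1, f_c2, Delta) within the corner-frequency and
    delay bounds, taking the best of ``n_starts`` bounded L-BFGS-B runs
    from randomized starting points (corner frequencies log-uniform, the
    delay drawn from a fixed ladder plus log-uniform values).  A pure
    lowpass filter (gamma2 = 0) is fitted from ``n_starts_lowpass`` starts
    for comparison; its solution also seeds one bandpass start, so the
    bandpass loss can never exceed the lowpass loss.  If the fit returns
    f_c1 > f_c2, frequencies are swapped and the gains remapped
    (gamma1 <- gamma1 gamma2, gamma2 <- 1/gamma2), which leaves the filter
    unchanged.
    """
    mask = np.isfinite(tf.H)
    f = tf.frequencies[mask]
    H0 = tf.H[mask]
    if f.size < 8:
        raise ValueError("need at least 8 valid transfer-function points")
    rng = np.random.default_rng(seed)
    umin, umax = np.log10(F_C_MIN), np.log10(F_C_MAX)
    gmax = max(2.0 * np.max(np.abs(H0)), 1.0)

    def random_start(k, lowpass):
        if k < len(_DELAY_LADDER):
            d = _DELAY_LADDER[k]
        else:
            d = 10.0 ** rng.uniform(np.log10(0.05), np.log10(DELAY_MAX))
        g1 = rng.uniform(-gmax, gmax)
        u1 = rng.uniform(umin, umax)
        if lowpass:
            return [g1, u1, d]
        return [g1, rng.uniform(-2.5, 2.5), u1, rng.uniform(umin, umax), d]

    def run(x0, lowpass):
        bounds = ([(-1e4, 1e4), (umin, umax), (0.0, DELAY_MAX)] if lowpass
                  else [(-1e4, 1e4), (-1e4, 1e4), (umin, umax), (umin, umax),
                        (0.0, DELAY_MAX)])
        return optimize.minimize(_filter_loss, x0, args=(f, H0, lowpass),
                                 method="L-BFGS-B", bounds=bounds)

    best_lp = None
    for k in range(n_starts_lowpass):
        res = run(random_start(k, True), True)
        if best_lp is None or res.fun < best_lp.fun:
            best_lp = res
    if best_lp is None:
        raise RuntimeError("all lowpass fit starts failed")
    g1, u1, d = best_lp.x
    lp_params = FilterParams(g1, 0.0, 10.0 ** u1, F_C_MAX, d)

    starts = [[g1, 0.0, u1, rng.uniform(umin, umax), d]]
    starts += [random_start(k, False) for k in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = run(x0, False)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all bandpass fit starts failed")
    g1, g2, u1, u2, d = best.x
    fc1, fc2 = 10.0 ** u1, 10.0 ** u2
    if fc1 > fc2:
        fc1, fc2 = fc2, fc1
        if abs(g2) > _GAMMA2_GUARD:
            g1, g2 = g1 * g2, 1.0 / g2
    params = FilterParams(g1, g2, fc1, fc2, d)
    return FilterFitResult(params=params, loss=float(best.fun),
                           lowpass_params=lp_params,
                           lowpass_loss=float(best_lp.fun))


def filter_kernel(p: FilterParams, dt: float = 0.1,
                  tail: float = 1e-12) -> np.ndarray:
    """Normalized kernel h as exact per-bin integrals on the dt grid.

    h(t) = Theta(t - Delta) [ e^{-(t-Delta)/tau1}/tau1
                              + gamma2 e^{-(t-Delta)/tau2}/tau2 ] / (1+gamma2),

    with tau_k = 1/(2 pi f_ck).  Each bin holds the analytic integral of
    h over the bin, so the kernel sums to 1 - O(``tail``) exactly and the
    discrete convolution with a piecewise-constant input is exact.
    """
    if abs(1.0 + p.gamma2) <= _GAMMA2_GUARD:
        raise ValueError("1 + gamma2 is numerically zero")
    tau1, tau2 = p.tau_c1, p.tau_c2
    n_delay = int(round(p.delay / dt))
    n_tail = int(np.ceil(-max(tau1, tau2) * np.log(tail) / dt)) + 1
    k = np.arange(n_tail)
    q1 = np.exp(-dt / tau1)
    q2 = np.exp(-dt / tau2)
    mass = ((1.0 - q1) * q1 ** k + p.gamma2 * (1.0 - q2) * q2 ** k) / (1.0 + p.gamma2)
    h = np.zeros(n_delay + n_tail)
    h[n_delay:] = mass
    return h


def predict_convolution(m: LNModel, a: np.ndarray, dt: float = 0.1) -> np.ndarray:
    """LN rate prediction r = max(0, g(h*a)) via FFT convolution.

    The input rate ``a`` (s^-1, on the dt grid) is edge-padded on the left
    with a[0], i.e. the filter state is warm-started at the fixed point of
    the initial rate.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("input rate must be non-negative")
    h = filter_kernel(m.filter, dt)
    a_pad = np.concatenate([np.full(h.size - 1, a[0]), a])
    u = signal.fftconvolve(a_pad, h, mode="valid")
    return np.maximum(0.0, m.activation(u))


def predict_ode(m: LNModel, a: np.ndarray, dt: float = 0.1) -> np.ndarray:
    """LN rate prediction via the equivalent two-variable ODE system.

    Linear chain trick: u1' = -u1/tau1 + a(t-Delta) c1/tau1 and
    u2' = -u2/tau2 + a(t-Delta) c2/tau2 with c1 = 1/(1+gamma2),
    c2 = gamma2/(1+gamma2); each variable is advanced with its exact
    exponential-integrator step (input constant over a bin), the delay is
    an input buffer, and r = max(0, g(u1+u2)).  States start at the fixed
    point of the initial rate.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("input rate must be non-negative")
    p = m.filter
    if abs(1.0 + p.gamma2) <= _GAMMA2_GUARD:
        raise ValueError("1 + gamma2 is numerically zero")
    n_delay = int(round(p.delay / dt))
    if n_delay > 0:
        a_d = np.concatenate([np.full(n_delay, a[0]), a[:-n_delay]])
    else:
        a_d = a
    c1 = 1.0 / (1.0 + p.gamma2)
    c2 = p.gamma2 / (1.0 + p.gamma2)
    u = np.zeros_like(a_d)
    for tau, c in ((p.tau_c1, c1), (p.tau_c2, c2)):
        q = np.exp(-dt / tau)
        zi = np.array([q * c * a_d[0]])
        ui, _ = signal.lfilter([c * (1.0 - q)], [1.0, -q], a_d, zi=zi)
        u += ui
    return np.maximum(0.0, m.activation(u))


def fit_ln_models(system, activation: ActivationFunction,
                  working_points: Sequence[Tuple[float, float]] = WORKING_POINTS,
                  n_trials: int = 1024, n_starts: int = 60,
                  n_starts_lowpass: int = 15,
                  frequencies: Optional[np.ndarray] = None,
                  min_duration: float = 1000.0,
                  seed: int = 0) -> Dict[Tuple[float, float], LNModel]:
    """Fit one LN model per working point (a0, a1) for a given condition.

    Measures the empirical transfer function at each working point, fits
    the bandpass filter, and pairs it with the condition's activation
    function.  Working points whose transfer-function estimate is invalid
    (insufficient spiking) are skipped.
    """
    models: Dict[Tuple[float, float], LNModel] = {}
    for j, (a0, a1) in enumerate(working_points):
        tf = measure_transfer_function(system, a0, a1,
                                       frequencies=frequencies,
                                       n_trials=n_trials,
                                       min_duration=min_duration,
                                       seed=seed + 104729 * j)
        if not tf.valid or np.sum(np.isfinite(tf.H)) < 8:
            continue
        fit = fit_filter(tf, n_starts=n_starts,
                         n_starts_lowpass=n_starts_lowpass,
                         seed=seed + 31 * j)
        meta = dict(tf.metadata)
        meta.update({"loss": fit.loss, "lowpass_loss": fit.lowpass_loss})
        models[(a0, a1)] = LNModel(activation=activation, filter=fit.params,
                                   metadata=meta)
    return models
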