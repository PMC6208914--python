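"""Izhikevich and AMAT spiking neuron simulators on a fixed 0.1 ms grid.

Two model classes are implemented:

* the two-variable quadratic **Izhikevich** model
  (v' = 0.04 v^2 + 5 v + 140 - u + I, u' = a(b v - u), hard reset
  v <- c, u <- u + d at v >= V_th), integrated with forward Euler;
* the **augmented multi-adaptive-threshold (AMAT)** model: a leaky
  integrator with exponential synaptic currents, integrated exactly
  (propagator step), whose spike threshold is omega plus two
  spike-triggered exponentially decaying components (tau_1, tau_2) plus a
  voltage-driven component with gain beta and time constant tau_V.  The
  membrane potential is *not* reset at spikes; an absolute refractory
  period tau_ref suppresses threshold crossings.

Parameter sets for the ~20 canonical firing-pattern variants of each class
(tonic/phasic spiking and bursting, resonator, bistability, ...) are
packaged as presets addressable by variant letter.

Units: the Izhikevich model treats all quantities except time (ms) and
membrane potential (mV) as unitless; AMAT uses mV, pA, pF, ms.  Input
weights are supplied fully multiplied out: for the Izhikevich class the
natural scale is the variant's weight factor ``xi`` (smallest single-spike
weight that triggers spiking from rest), for AMAT the class-wide threshold
weight ``w_theta`` (see :func:`compute_w_theta_amat`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .trains import SpikeTrain

__all__ = [
    "IzhikevichParams",
    "AMATParams",
    "SimulationConfig",
    "StateTrace",
    "ModelSpec",
    "NOISE_PRESETS",
    "noise_regime",
    "izhikevich_params",
    "amat_params",
    "list_variants",
    "simulate_izhikevich",
    "simulate_amat",
    "compute_w_theta_amat",
    "gaussian_noise_current",
    "population_counts",
    "stimulus_weight",
]

#: background-noise regimes; (mu, sigma) in unitless current for the
#: Izhikevich class and in pA for the AMAT class
NOISE_PRESETS = {
    "none": {"izhikevich": (0.0, 0.0), "amat": (0.0, 0.0)},
    "balanced": {"izhikevich": (0.0, 0.1), "amat": (0.0, 100.0)},
    "biased": {"izhikevich": (-0.1, 0.2), "amat": (-100.0, 200.0)},
}

#: synaptic weights for the AMAT background-noise Poisson inputs (pA)
W_E_BG = 1.0
W_I_BG = -4.0 / 3.0


@dataclass(frozen=True)
class IzhikevichParams:
    a: float
    b: float
    c: float
    d: float
    xi: float
    I_ext: float = 0.0
    V_th: float = 30.0
    label: str = ""
    name: str = ""

    def __post_init__(self):
        if self.xi <= 0:
            raise ValueError("weight factor xi must be positive")


@dataclass(frozen=True)
class AMATParams:
    alpha1: float
    alpha2: float
    beta: float
    E_L: float = -70.0
    omega: float = -65.0
    C_m: float = 200.0
    tau_m: float = 10.0
    tau_1: float = 10.0
    tau_2: float = 200.0
    tau_V: float = 5.0
    tau_ref: float = 2.0
    tau_syn_E: float = 1.0
    tau_syn_I: float = 3.0
    label: str = ""
    name: str = ""


@dataclass
class SimulationConfig:
    """Grid and bookkeeping options shared by both simulators."""

    T: float
    dt: float = 0.1
    equilibration: float = 1000.0
    seed: int = 0
    record_voltage: bool = False
    n_substeps: int = 1  # Izhikevich only; >1 reproduces historic substepping

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T <= 0:
            raise ValueError("duration T must be positive")
        if self.equilibration < 0:
            raise ValueError("equilibration must be non-negative")

    @property
    def n_steps_total(self) -> int:
        return int(round((self.equilibration + self.T) / self.dt))

    @property
    def n_steps_equil(self) -> int:
        return int(round(self.equilibration / self.dt))


@dataclass
class StateTrace:
    """Recorded state channels on the simulation grid plus the final state.

    ``time`` is absolute simulation time in ms (equilibration included);
    ``channels`` maps channel name (e.g. ``"V"``) to an array on that grid.
    ``final_state`` always holds the state at the end of the run so that a
    simulation can be split and resumed.
    """

    time: np.ndarray
    channels: dict = field(default_factory=dict)
    final_state: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ModelSpec:
    """Reference to one neuron-model variant, e.g. ``ModelSpec("amat", "A")``."""

    model_class: str
    variant: str

    def __post_init__(self):
        if self.model_class not in ("izhikevich", "amat"):
            raise ValueError(f"unknown model class {self.model_class!r}")

    @property
    def params(self):
        if self.model_class == "izhikevich":
            return izhikevich_params(self.variant)
        return amat_params(self.variant)

    def __str__(self):
        return f"{self.model_class}:{self.variant}"


def _load_presets() -> dict:
    with resources.files("lnrate").joinpath("_presets.json").open() as fh:
        return json.load(fh)


_PRESETS = _load_presets()


def izhikevich_params(variant: str) -> IzhikevichParams:
    """Parameters of one included Izhikevich variant (letters A..S)."""
    try:
        row = _PRESETS["izhikevich"][variant]
    except KeyError:
        raise KeyError(f"unknown or excluded Izhikevich variant {variant!r}") from None
    return IzhikevichParams(a=row["a"], b=row["b"], c=row["c"], d=row["d"],
                            xi=row["xi"], I_ext=row["I_ext"],
                            label=variant, name=row["name"])


def amat_params(variant: str) -> AMATParams:
    """Parameters of one included AMAT variant (letters A..T)."""
    try:
        row = _PRESETS["amat"][variant]
    except KeyError:
        raise KeyError(f"unknown or excluded AMAT variant {variant!r}") from None
    return AMATParams(alpha1=row["alpha1"], alpha2=row["alpha2"],
                      beta=row["beta"], label=variant, name=row["name"])


def list_variants(model_class: str) -> list:
    return sorted(_PRESETS[model_class])


def noise_regime(preset, model_class: str) -> tuple:
    """Resolve a noise preset name or explicit (mu, sigma) pair."""
    if isinstance(preset, str):
        try:
            return NOISE_PRESETS[preset][model_class]
        except KeyError:
            raise KeyError(f"unknown noise preset {preset!r}") from None
    mu, sigma = preset
    return float(mu), float(sigma)


def gaussian_noise_current(mu: float, sigma: float, dt: float, T: float,
                           seed: int) -> np.ndarray:
    """Piecewise-constant noise current, redrawn independently every step.

    The standard deviation applies per step as given (no 1/sqrt(dt)
    scaling), so the effective diffusion depends on dt; the packaged noise
    presets assume dt = 0.1 ms.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    n = int(round(T / dt))
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return np.full(n, mu)
    return mu + sigma * rng.standard_normal(n)


def _input_arrays(input_spikes, current, n_steps, dt, extra=0.0):
    """Accumulate (time, weight) events onto the grid; floor-snap times."""
    w_in = np.zeros(n_steps)
    if input_spikes is not None:
        for t_ms, w in input_spikes:
            k = int(np.floor(t_ms / dt + 1e-9))
            if not 0 <= k < n_steps:
                raise ValueError(f"input spike at {t_ms} ms outside the grid")
            w_in[k] += w
    if current is None:
        I = np.full(n_steps, extra)
    elif np.isscalar(current):
        I = np.full(n_steps, float(current) + extra)
    else:
        current = np.asarray(current, dtype=float)
        if current.shape[0] != n_steps:
            raise ValueError(
                f"current trace has {current.shape[0]} samples, expected {n_steps}")
        I = current + extra
    return w_in, I


def simulate_izhikevich(params: IzhikevichParams, input_spikes=None,
                        current=None, noise=None,
                        config: SimulationConfig = None,
                        initial_state: Optional[tuple] = None):
    """Simulate one Izhikevich neuron.

    Parameters
    ----------
    input_spikes
        Iterable of ``(time_ms, weight)``; times are floor-snapped to the
        grid and counted from the start of the simulation (equilibration
        included).  Weights are absolute (fractions of xi multiplied out).
    current, noise
        Scalar or per-step arrays over the full grid; both are added to
        ``params.I_ext``.
    initial_state
        ``(v0, u0)``; default v0 ~ U(-70, 30), u0 = b v0, seeded from
        ``config.seed``.

    Returns
    -------
    (SpikeTrain, StateTrace)
        Spike times relative to the end of the equilibration period; the
        trace covers the full grid (absolute time) when
        ``config.record_voltage`` and always carries ``final_state``.
    """
    cfg = config
    n_steps = cfg.n_steps_total
    w_in, I = _input_arrays(input_spikes, current, n_steps, cfg.dt,
                            extra=params.I_ext)
    if noise is not None:
        noise = np.asarray(noise, dtype=float)
        if noise.shape[0] != n_steps:
            raise ValueError("noise trace length mismatch")
        I = I + noise
    if initial_state is None:
        rng = np.random.default_rng(cfg.seed)
        v0 = -70.0 + 100.0 * rng.random()
        u0 = params.b * v0
    else:
        v0, u0 = map(float, initial_state)
    rec = bool(cfg.record_voltage)
    v_tr = np.empty(n_steps if rec else 1)
    u_tr = np.empty(n_steps if rec else 1)
    spike_steps = np.empty(n_steps, dtype=np.int64)
    ns, err, v, u = _kernels.izh_single(
        params.a, params.b, params.c, params.d, params.V_th, cfg.dt,
        cfg.n_substeps, w_in, I, v0, u0, rec, v_tr, u_tr, spike_steps)
    if err >= 0:
        raise FloatingPointError(
            f"Izhikevich state diverged at t = {err * cfg.dt:.1f} ms")
    t_spk = spike_steps[:ns] * cfg.dt - cfg.equilibration
    t_spk = t_spk[t_spk >= 0]
    train = SpikeTrain(np.round(t_spk / cfg.dt) * cfg.dt, t_start=0.0, t_stop=cfg.T)
    trace = StateTrace(time=np.arange(n_steps) * cfg.dt,
                       channels={"V": v_tr, "u": u_tr} if rec else {},
                       final_state={"v": v, "u": u})
    return train, trace


def simulate_amat(params: AMATParams, input_spikes=None, current=None,
                  noise_spikes=None, config: SimulationConfig = None,
                  initial_state: Optional[dict] = None):
    """Simulate one AMAT neuron (exact integration).

    ``input_spikes`` is an iterable of ``(time_ms, weight_pA)``; positive
    weights are delivered through the excitatory synapse (tau_syn_E),
    negative through the inhibitory synapse (tau_syn_I).  ``noise_spikes``
    takes the same format (background events with fixed small weights).
    ``initial_state`` may carry V, i_E, i_I, th1, th2, thV and t_last (ms,
    relative to simulation start; -inf for "never").
    """
    cfg = config
    n_steps = cfg.n_steps_total
    events = list(input_spikes) if input_spikes is not None else []
    if noise_spikes is not None:
        events = events + list(noise_spikes)
    wE_in = np.zeros(n_steps)
    wI_in = np.zeros(n_steps)
    for t_ms, w in events:
        k = int(np.floor(t_ms / cfg.dt + 1e-9))
        if not 0 <= k < n_steps:
            raise ValueError(f"input spike at {t_ms} ms outside the grid")
        if w >= 0:
            wE_in[k] += w
        else:
            wI_in[k] += w
    _, I = _input_arrays(None, current, n_steps, cfg.dt)
    if initial_state is None:
        rng = np.random.default_rng(cfg.seed)
        state = {"V": params.E_L + (params.omega - params.E_L) * rng.random(),
                 "i_E": 0.0, "i_I": 0.0, "th1": 0.0, "th2": 0.0, "thV": 0.0,
                 "t_last": -np.inf}
    else:
        state = dict(initial_state)
    last0 = state.get("t_last", -np.inf)
    ref_steps = int(round(params.tau_ref / cfg.dt))
    last_step = (-10 * n_steps - 10 * ref_steps if not np.isfinite(last0)
                 else int(round(last0 / cfg.dt)))
    rec = bool(cfg.record_voltage)
    V_tr = np.empty(n_steps if rec else 1)
    th_tr = np.empty(n_steps if rec else 1)
    spike_steps = np.empty(max(n_steps // ref_steps + 1, 1), dtype=np.int64)
    ns, err, V, iE, iI, th1, th2, thV, last = _kernels.amat_single(
        params.alpha1, params.alpha2, params.beta, params.E_L, params.omega,
        params.C_m, params.tau_m, params.tau_1, params.tau_2, params.tau_V,
        params.tau_ref, params.tau_syn_E, params.tau_syn_I, cfg.dt,
        wE_in, wI_in, I,
        state.get("V", params.E_L), state.get("i_E", 0.0),
        state.get("i_I", 0.0), state.get("th1", 0.0), state.get("th2", 0.0),
        state.get("thV", 0.0), last_step, rec, V_tr, th_tr, spike_steps)
    if err >= 0:
        raise FloatingPointError(
            f"AMAT state diverged at t = {err * cfg.dt:.1f} ms")
    t_spk = spike_steps[:ns] * cfg.dt - cfg.equilibration
    t_spk = t_spk[t_spk >= 0]
    train = SpikeTrain(np.round(t_spk / cfg.dt) * cfg.dt, t_start=0.0, t_stop=cfg.T)
    final = {"V": V, "i_E": iE, "i_I": iI, "th1": th1, "th2": th2,
             "thV": thV,
             "t_last": last * cfg.dt - n_steps * cfg.dt if last > -n_steps
             else -np.inf}
    # t_last in final state is relative to the *end* of this run
    trace = StateTrace(time=np.arange(n_steps) * cfg.dt,
                       channels={"V": V_tr, "theta": th_tr} if rec else {},
                       final_state=final)
    return train, trace


def compute_w_theta_amat(params: AMATParams) -> float:
    """Minimal excitatory weight whose single-spike PSP reaches threshold.

    Computed against the static resting threshold omega (the
    voltage-driven component is ignored), so the value is identical across
    all packaged variants: the subthreshold dynamics are linear and shared.
    The PSP of a weight-w spike through the excitatory synapse peaks at

        w * (tau_E tau_m) / (C_m (tau_E - tau_m)) *
            (exp(-t*/tau_E) - exp(-t*/tau_m)),

    with t* = ln(tau_m/tau_E) / (1/tau_E - 1/tau_m).
    """
    gap = params.omega - params.E_L
    if gap <= 0:
        raise ValueError("omega must lie above E_L")
    tau_s, tau_m, C = params.tau_syn_E, params.tau_m, params.C_m
    t_star = np.log(tau_m / tau_s) / (1.0 / tau_s - 1.0 / tau_m)
    peak = (tau_s * tau_m) / (C * (tau_s - tau_m)) * (
        np.exp(-t_star / tau_s) - np.exp(-t_star / tau_m))
    return gap / peak


def stimulus_weight(spec: ModelSpec, w: float) -> float:
    """Absolute synaptic weight for a condition-level weight ``w``.

    For the AMAT class ``w`` is already in pA; for the Izhikevich class
    ``w`` is a fraction of the variant's weight factor xi (the convention
    in which the weight sweep 0.1 .. 0.75 is expressed).
    """
    if spec.model_class == "izhikevich":
        return w * spec.params.xi
    return w


def population_counts(spec: ModelSpec, rate, w: float, noise="none",
                      n: int = 1, T: float = None, dt: float = 0.1,
                      equilibration: float = 1000.0, seed: int = 0,
                      fixed_weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Pooled per-bin output spike counts of ``n`` independent neurons.

    Each neuron is driven by its own Poisson stimulus train with rate
    profile ``rate`` (scalar s^-1 or per-step array over the *full* grid,
    equilibration included) and synaptic weight ``w`` (fraction of xi for
    Izhikevich, pA for AMAT), plus the background-noise regime ``noise``
    (preset name or (mu, sigma)).  Alternatively, ``fixed_weights`` (shape
    ``(n, total steps)``, input-spike counts per bin) freezes the stimulus:
    neuron i then receives exactly those events with weight ``w`` and only
    noise and initial conditions vary with the seed.  Returns int64 counts
    for the recording window only.
    """
    from .stimuli import solve_background_rates  # deferred: keep modules acyclic

    if n < 1:
        raise ValueError("population size must be >= 1")
    n_equil = int(round(equilibration / dt))
    if np.isscalar(rate):
        if T is None and fixed_weights is None:
            raise ValueError("T is required with a scalar rate")
        n_total = (fixed_weights.shape[1] if fixed_weights is not None
                   else n_equil + int(round(T / dt)))
        rate_arr = np.full(n_total, float(rate))
    else:
        rate_arr = np.asarray(rate, dtype=float)
        n_total = rate_arr.shape[0]
        if n_total <= n_equil:
            raise ValueError("rate array must extend beyond the equilibration")
    p = rate_arr * dt * 1e-3
    if np.any(p > 1.0):
        raise ValueError("rate too high for the grid: a(t)*dt > 1")
    use_fixed = fixed_weights is not None
    if use_fixed:
        w_fixed = np.ascontiguousarray(fixed_weights, dtype=float)
        if w_fixed.shape != (n, n_total):
            raise ValueError("fixed_weights must have shape (n, total steps)")
    else:
        w_fixed = np.zeros((1, 1))
    counts = np.zeros(n_total - n_equil, dtype=np.int64)
    mu, sigma = noise_regime(noise, spec.model_class)
    seed = int(seed) % (2**31 - 1)
    if spec.model_class == "izhikevich":
        prm = spec.params
        _kernels.izh_population(prm.a, prm.b, prm.c, prm.d, prm.V_th,
                                prm.I_ext, dt, p, w * prm.xi, mu, sigma,
                                sigma > 0 or mu != 0, n, seed, n_equil,
                                counts, use_fixed, w_fixed)
    else:
        prm = spec.params
        use_bg = sigma > 0 or mu != 0
        if use_bg:
            nu_E, nu_I = solve_background_rates(mu, sigma)
            lam_E, lam_I = nu_E * dt * 1e-3, nu_I * dt * 1e-3
        else:
            lam_E = lam_I = 0.0
        _kernels.amat_population(prm.alpha1, prm.alpha2, prm.beta, prm.E_L,
                                 prm.omega, prm.C_m, prm.tau_m, prm.tau_1,
                                 prm.tau_2, prm.tau_V, prm.tau_ref,
                                 prm.tau_syn_E, prm.tau_syn_I, dt, p, w,
                                 lam_E, lam_I, W_E_BG, W_I_BG, use_bg,
                                 n, seed, n_equil, counts, use_fixed, w_fixed)
    return counts
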