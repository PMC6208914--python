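"""Stimulus ensembles: sinusoidal and stepped Poisson trains, background
noise-rate inversion, and synthetic retinal-ganglion-cell-like trains.

All Poisson generators use the grid-based Bernoulli dialect: one draw per
dt bin with success probability a(t)*dt.  An exact time-rescaling
alternative is available via ``dialect="exact"`` for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .trains import SpikeTrain

__all__ = [
    "SinusoidalRate",
    "RateSchedule",
    "BackgroundNoiseSpec",
    "DEFAULT_STEP_SCHEDULE",
    "sinusoidal_poisson_train",
    "piecewise_poisson_train",
    "solve_background_rates",
    "synth_rgc_trains",
    "default_rgc_events",
    "rgc_event_amplitude",
    "merge_train_pairs",
]


@dataclass(frozen=True)
class SinusoidalRate:
    """Rate profile a(t) = a0 + a1 sin(2 pi f_stim t), in s^-1 / Hz."""

    a0: float
    a1: float
    f_stim: float

    def __post_init__(self):
        if not 0 <= self.a1 <= self.a0:
            raise ValueError("modulation depth must satisfy 0 <= a1 <= a0")
        if self.f_stim < 0:
            raise ValueError("f_stim must be non-negative")

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        return self.a0 + self.a1 * np.sin(2e-3 * np.pi * self.f_stim * np.asarray(t_ms))


@dataclass(frozen=True)
class RateSchedule:
    """Contiguous piecewise-constant rate profile.

    ``intervals`` is a sequence of (t_start_ms, t_end_ms, rate_s) covering
    [0, T) exactly, without gaps or overlaps.
    """

    intervals: Tuple[Tuple[float, float, float], ...]

    def __post_init__(self):
        iv = tuple(tuple(map(float, row)) for row in self.intervals)
        object.__setattr__(self, "intervals", iv)
        if not iv:
            raise ValueError("schedule must contain at least one interval")
        t = 0.0
        for t0, t1, r in iv:
            if abs(t0 - t) > 1e-9:
                raise ValueError(f"interval starting at {t0} ms leaves a gap/overlap")
            if t1 <= t0:
                raise ValueError("intervals must have positive length")
            if r < 0:
                raise ValueError("rates must be non-negative")
            t = t1

    @property
    def T(self) -> float:
        return self.intervals[-1][1]

    def rate_array(self, dt: float) -> np.ndarray:
        """Rate in s^-1 sampled on the dt grid over [0, T)."""
        n = int(round(self.T / dt))
        t = np.arange(n) * dt
        out = np.empty(n)
        for t0, t1, r in self.intervals:
            out[(t >= t0 - 1e-9) & (t < t1 - 1e-9)] = r
        return out


#: stepped-Poisson test stimulus: 100/200/40/150 s^-1 over 1.5 s
DEFAULT_STEP_SCHEDULE = RateSchedule((
    (0.0, 600.0, 100.0),
    (600.0, 1000.0, 200.0),
    (1000.0, 1200.0, 40.0),
    (1200.0, 1500.0, 150.0),
))


@dataclass(frozen=True)
class BackgroundNoiseSpec:
    """Poisson background-input specification for the AMAT class.

    Excitatory/inhibitory event rates nu_E, nu_I (s^-1) with fixed weights
    w_E = 1 pA, w_I = -4/3 pA and synaptic time constants 1 ms / 3 ms give
    a noise current of mean mu_bg and standard deviation sigma_bg:

        mu_bg     = w_E nu_E tau_E + w_I nu_I tau_I
        sigma_bg^2 = (w_E^2 nu_E tau_E + w_I^2 nu_I tau_I) / 2
    """

    mu_bg: float
    sigma_bg: float
    w_E_bg: float = 1.0
    w_I_bg: float = -4.0 / 3.0
    tau_syn_E: float = 1.0
    tau_syn_I: float = 3.0
    nu_E: float = field(init=False, default=0.0)
    nu_I: float = field(init=False, default=0.0)

    def __post_init__(self):
        nu_E, nu_I = solve_background_rates(
            self.mu_bg, self.sigma_bg,
            weights=(self.w_E_bg, self.w_I_bg),
            taus=(self.tau_syn_E, self.tau_syn_I))
        object.__setattr__(self, "nu_E", nu_E)
        object.__setattr__(self, "nu_I", nu_I)


def solve_background_rates(mu_bg: float, sigma_bg: float,
                           weights: Tuple[float, float] = (1.0, -4.0 / 3.0),
                           taus: Tuple[float, float] = (1.0, 3.0)):
    """Invert the (mu_bg, sigma_bg) relations for (nu_E, nu_I) in s^-1.

    Both relations are linear in the rates, so this is an exact 2x2 solve;
    weights in pA, time constants in ms, mu in pA, sigma in pA.
    """
    wE, wI = weights
    tE, tI = taus[0] * 1e-3, taus[1] * 1e-3  # s
    A = np.array([[wE * tE, wI * tI],
                  [wE * wE * tE / 2.0, wI * wI * tI / 2.0]])
    b = np.array([mu_bg, sigma_bg ** 2])
    nu = np.linalg.solve(A, b)
    nu[np.abs(nu) < 1e-12] = 0.0
    if np.any(nu < 0):
        raise ValueError(
            f"no non-negative rate solution: nu_E={nu[0]:.3g}, nu_I={nu[1]:.3g}")
    return float(nu[0]), float(nu[1])


def _bernoulli_train(rate_arr: np.ndarray, dt: float, rng) -> np.ndarray:
    p = rate_arr * dt * 1e-3
    if np.any(p > 1.0):
        raise ValueError("rate too high for the grid: a(t)*dt > 1")
    idx = np.nonzero(rng.random(p.shape[0]) < p)[0]
    return idx * dt


def sinusoidal_poisson_train(rate: SinusoidalRate, T: float, dt: float = 0.1,
                             seed: int = 0, dialect: str = "bernoulli") -> SpikeTrain:
    """One inhomogeneous Poisson train with sinusoidally modulated rate.

    ``dialect="bernoulli"`` (default) draws once per dt bin with
    p = a(t) dt; ``dialect="exact"`` uses time-rescaling thinning and is
    provided for distributional cross-checks.
    """
    rng = np.random.default_rng(seed)
    if dialect == "bernoulli":
        n = int(round(T / dt))
        t = np.arange(n) * dt
        times = _bernoulli_train(rate(t), dt, rng)
    elif dialect == "exact":
        lam_max = (rate.a0 + rate.a1) * 1e-3  # ms^-1
        n_exp = rng.poisson(lam_max * T)
        cand = np.sort(rng.random(n_exp) * T)
        keep = rng.random(n_exp) * lam_max < rate(cand) * 1e-3
        times = np.unique(cand[keep])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return SpikeTrain(times, t_start=0.0, t_stop=T)


def piecewise_poisson_train(schedule: RateSchedule, dt: float = 0.1,
                            seed: int = 0) -> SpikeTrain:
    """Bernoulli-per-bin inhomogeneous Poisson train for a rate schedule."""
    rng = np.random.default_rng(seed)
    times = _bernoulli_train(schedule.rate_array(dt), dt, rng)
    return SpikeTrain(times, t_start=0.0, t_stop=schedule.T)


def default_rgc_events(T: float = 8000.0, n_events: int = 12) -> np.ndarray:
    """Default transient-event times (ms): evenly spread, clear of edges."""
    return np.linspace(0.04 * T, 0.96 * T, n_events)


def rgc_event_amplitude(target_mean: float, baseline_rate: float, T: float,
                        n_events: int, event_width: float) -> float:
    """Gaussian-bump amplitude (s^-1) so the mean train rate hits target.

    Each transient contributes amp * sqrt(2 pi) * width expected spikes.
    """
    excess = target_mean - baseline_rate
    if excess < 0:
        raise ValueError("baseline exceeds the target mean rate")
    per_event = excess * (T * 1e-3) / n_events
    return per_event / (np.sqrt(2.0 * np.pi) * event_width * 1e-3)


def synth_rgc_trains(n_trains: int = 96, T: float = 8000.0,
                     baseline_rate: float = 8.0,
                     event_times: Optional[Sequence[float]] = None,
                     event_amplitude: Optional[float] = None,
                     event_width: float = 15.0,
                     dt: float = 0.1, seed: int = 0) -> List[SpikeTrain]:
    """Synthetic retinal-ganglion-cell-like spike trains.

    Emulates recordings with low baseline firing and fast transients:
    inhomogeneous Poisson trains whose rate is a constant baseline plus
    Gaussian bumps of width ``event_width`` (ms, the Gaussian sigma) at
    ``event_times``.  The default amplitude is calibrated analytically so
    the grand-mean single-train rate is 18.3 s^-1 for the default 96
    trains of 8 s.
    """
    if n_trains < 1 or T <= 0 or baseline_rate < 0 or event_width <= 0:
        raise ValueError("invalid synthetic-RGC parameters")
    ev = np.asarray(event_times if event_times is not None
                    else default_rgc_events(T), dtype=float)
    if event_amplitude is None:
        event_amplitude = rgc_event_amplitude(18.3, baseline_rate, T,
                                              ev.size, event_width)
    n = int(round(T / dt))
    t = np.arange(n) * dt
    rate = np.full(n, float(baseline_rate))
    for te in ev:
        rate += event_amplitude * np.exp(-0.5 * ((t - te) / event_width) ** 2)
    rng = np.random.default_rng(seed)
    return [SpikeTrain(_bernoulli_train(rate, dt, rng), t_start=0.0, t_stop=T)
            for _ in range(n_trains)]


def merge_train_pairs(trains: Sequence[SpikeTrain]) -> List[SpikeTrain]:
    """Merge consecutive pairs of trains (sorted union of spike times).

    Halves the train count and doubles per-train rates; the total spike
    count is conserved.  Coincident spikes (same grid bin in both trains)
    are kept distinct by shifting the later one by 1 us, well below the
    grid resolution.
    """
    if len(trains) % 2:
        raise ValueError("merging requires an even number of trains")
    out = []
    for a, b in zip(trains[::2], trains[1::2]):
        if (a.t_start, a.t_stop) != (b.t_start, b.t_stop):
            raise ValueError("trains must share a common time window")
        times = np.sort(np.concatenate([a.times, b.times]))
        dup = np.nonzero(np.diff(times) == 0)[0]
        times[dup + 1] += 1e-3
        out.append(SpikeTrain(np.sort(times), t_start=a.t_start,
                              t_stop=a.t_stop))
    return out
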