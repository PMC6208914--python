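"""Shared fixtures and independent pure-Python oracles.

The oracles deliberately re-implement the simulator update rules as plain
Python loops (no numpy vectorization, no compilation) so that the compiled
simulators can be checked against an independent transcription of the same
dynamics.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from lnrate.neuron_models import SimulationConfig


def izh_euler_oracle(a, b, c, d, vth, dt, n_sub, w_in, I_in, v0, u0):
    """Direct-translation forward-Euler loop for the Izhikevich model.

    Mirrors the documented update order: add input weight, n_sub membrane
    substeps, one recovery step using the updated v, then threshold/reset.
    Returns (spike_steps, v, u).
    """
    v, u = v0, u0
    h = dt / n_sub
    spikes = []
    for t in range(len(w_in)):
        v += w_in[t]
        I = I_in[t]
        for _ in range(n_sub):
            v = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
        u = u + dt * a * (b * v - u)
        if v >= vth:
            spikes.append(t)
            v = c
            u = u + d
    return spikes, v, u


def amat_psp_analytic(t, w, tau_s, tau_m, C_m):
    """Closed-form PSP of an exponential current pulse into a leaky membrane.

    Voltage deviation at time t >= 0 after a spike of weight w (pA) through
    a synapse with time constant tau_s, for a membrane with tau_m and C_m;
    the double-exponential difference of the two decay terms.
    """
    A = w * tau_s * tau_m / (C_m * (tau_s - tau_m))
    return A * (np.exp(-t / tau_s) - np.exp(-t / tau_m))


def kde_cost_bruteforce(times, width):
    """Fixed-kernel KDE cost from the raw pairwise spike-time distances."""
    t = np.asarray(times, dtype=float)
    n = t.size
    d = t[:, None] - t[None, :]
    k2 = np.exp(-d ** 2 / (4.0 * width ** 2)) / (2.0 * math.sqrt(math.pi) * width)
    kw = np.exp(-d ** 2 / (2.0 * width ** 2)) / (math.sqrt(2.0 * math.pi) * width)
    s1 = k2.sum()
    s2 = kw.sum() - n / (math.sqrt(2.0 * math.pi) * width)
    return s1 - 2.0 * s2


@pytest.fixture
def quick_config():
    """1 s run, no equilibration, deterministic initial state downstream."""
    return SimulationConfig(T=1000.0, equilibration=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
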