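"""Compiled inner loops for the spiking neuron simulators.

All kernels operate on the fixed simulation grid (step ``dt``, default
0.1 ms).  Single-neuron kernels are fully deterministic and take explicit
per-step input arrays; population kernels draw Poisson stimulus input and
background noise internally from a seeded generator and accumulate pooled
per-bin output spike counts.

State-update conventions (mirrored by the pure-Python test oracles):

Izhikevich (forward Euler, order as in the original published code):
    1. add incoming spike weights to v (instantaneous jumps),
    2. v += dt/n_sub * (0.04 v^2 + 5 v + 140 - u + I)   (n_sub substeps),
    3. u += dt * a * (b v - u)                          (uses updated v),
    4. if v >= V_th: record spike, v <- c, u <- u + d.

AMAT (exact integration of the linear subthreshold system):
    1. add incoming spike weights to the synaptic currents (jump at t),
    2. threshold test at time t: spike iff V >= omega + th1 + th2 + thV
       and at least tau_ref has passed since the last spike; on a spike
       th1 += alpha1, th2 += alpha2 (no membrane reset),
    3. propagate state t -> t+dt with exact exponential propagators;
       the voltage-driven threshold component thV uses exponential Euler
       with V frozen at its value at time t.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "izh_single",
    "izh_population",
    "amat_single",
    "amat_population",
]


@njit(cache=True)
def izh_single(a, b, c, d, vth, dt, n_sub, w_in, I_in, v0, u0,
               record, v_trace, u_trace, spike_steps):
    """Simulate one Izhikevich neuron; returns (n_spikes, err_step, v, u).

    ``w_in`` and ``I_in`` are per-step input-weight sums and total injected
    current (I_ext + stimulus + noise).  ``err_step`` is -1 unless the state
    became non-finite.
    """
    v = v0
    u = u0
    n_steps = w_in.shape[0]
    ns = 0
    h = dt / n_sub
    for t in range(n_steps):
        v += w_in[t]
        I = I_in[t]
        for _ in range(n_sub):
            v = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
        u = u + dt * a * (b * v - u)
        if not (np.isfinite(v) and np.isfinite(u)):
            return ns, t, v, u
        if v >= vth:
            spike_steps[ns] = t
            ns += 1
            v = c
            u = u + d
        if record:
            v_trace[t] = v
            u_trace[t] = u
    return ns, -1, v, u


@njit(cache=True)
def izh_population(a, b, c, d, vth, I_ext, dt, p_spike, weight,
                   noise_mu, noise_sigma, use_noise, n, seed, equil_steps,
                   counts, use_fixed, w_fixed):
    """Pooled response of ``n`` independent Izhikevich neurons.

    Each neuron receives its own Bernoulli-per-bin Poisson stimulus train
    (success probability ``p_spike[t]``, synaptic weight ``weight``) and, if
    ``use_noise``, an independent Gaussian noise current redrawn every step.
    With ``use_fixed``, neuron i instead receives the per-step weights
    ``w_fixed[i, t]`` (frozen input trains).  ``counts`` (length = total
    steps - equil_steps) accumulates pooled spike counts per bin after the
    equilibration period.  v(0) ~ U(-70, 30), u(0) = b v(0).
    """
    np.random.seed(seed)
    n_steps = p_spike.shape[0]
    for i in range(n):
        v = -70.0 + 100.0 * np.random.random()
        u = b * v
        for t in range(n_steps):
            if use_fixed:
                v += w_fixed[i, t] * weight
            elif np.random.random() < p_spike[t]:
                v += weight
            I = I_ext
            if use_noise:
                I += noise_mu + noise_sigma * np.random.standard_normal()
            v = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
            u = u + dt * a * (b * v - u)
            if v >= vth:
                if t >= equil_steps:
                    counts[t - equil_steps] += 1
                v = c
                u = u + d
    return 0


@njit(cache=True)
def amat_single(alpha1, alpha2, beta, E_L, omega, C_m,
                tau_m, tau_1, tau_2, tau_V, tau_ref, tau_E, tau_I, dt,
                wE_in, wI_in, I_in,
                V0, iE0, iI0, th10, th20, thV0, last0,
                record, V_trace, th_trace, spike_steps):
    """Simulate one AMAT neuron; returns (n_spikes, err_step, state tuple).

    ``last0`` is the step index of the most recent spike relative to step 0
    (use a large negative value for "never"), enabling state carry-over
    across split runs.
    """
    pm = np.exp(-dt / tau_m)
    pe = np.exp(-dt / tau_E)
    pi = np.exp(-dt / tau_I)
    p1 = np.exp(-dt / tau_1)
    p2 = np.exp(-dt / tau_2)
    pv = np.exp(-dt / tau_V)
    pVE = (tau_E * tau_m) / (C_m * (tau_E - tau_m)) * (pe - pm)
    pVI = (tau_I * tau_m) / (C_m * (tau_I - tau_m)) * (pi - pm)
    pVc = tau_m / C_m * (1.0 - pm)
    ref_steps = int(round(tau_ref / dt))

    V = V0
    iE = iE0
    iI = iI0
    th1 = th10
    th2 = th20
    thV = thV0
    last = last0
    ns = 0
    n_steps = wE_in.shape[0]
    for t in range(n_steps):
        iE += wE_in[t]
        iI += wI_in[t]
        if record:
            V_trace[t] = V
            th_trace[t] = omega + th1 + th2 + thV
        if t - last >= ref_steps and V >= omega + th1 + th2 + thV:
            spike_steps[ns] = t
            ns += 1
            th1 += alpha1
            th2 += alpha2
            last = t
        Vp = V
        V = E_L + (V - E_L) * pm + iE * pVE + iI * pVI + I_in[t] * pVc
        if not np.isfinite(V):
            return ns, t, V, iE, iI, th1, th2, thV, last
        thV = thV * pv + beta * (Vp - E_L) * (1.0 - pv)
        th1 *= p1
        th2 *= p2
        iE *= pe
        iI *= pi
    return ns, -1, V, iE, iI, th1, th2, thV, last


@njit(cache=True)
def amat_population(alpha1, alpha2, beta, E_L, omega, C_m,
                    tau_m, tau_1, tau_2, tau_V, tau_ref, tau_E, tau_I, dt,
                    p_spike, weight, lam_E, lam_I, wE_bg, wI_bg, use_bg,
                    n, seed, equil_steps, counts, use_fixed, w_fixed):
    """Pooled response of ``n`` independent AMAT neurons.

    Stimulus: Bernoulli-per-bin Poisson train of weight ``weight`` (pA) on
    the excitatory synapse (or, with ``use_fixed``, the frozen per-step
    input-spike counts ``w_fixed[i, t]`` times ``weight``).  Background:
    independent Poisson spike counts per bin with expectations
    ``lam_E``/``lam_I`` and fixed weights ``wE_bg``/``wI_bg`` delivered
    through the excitatory/inhibitory synapse, respectively.
    V(0) ~ U(E_L, omega).
    """
    pm = np.exp(-dt / tau_m)
    pe = np.exp(-dt / tau_E)
    pi = np.exp(-dt / tau_I)
    p1 = np.exp(-dt / tau_1)
    p2 = np.exp(-dt / tau_2)
    pv = np.exp(-dt / tau_V)
    pVE = (tau_E * tau_m) / (C_m * (tau_E - tau_m)) * (pe - pm)
    pVI = (tau_I * tau_m) / (C_m * (tau_I - tau_m)) * (pi - pm)
    ref_steps = int(round(tau_ref / dt))
    np.random.seed(seed)
    n_steps = p_spike.shape[0]
    big = -10 * n_steps - 10 * ref_steps
    for i in range(n):
        V = E_L + (omega - E_L) * np.random.random()
        iE = 0.0
        iI = 0.0
        th1 = 0.0
        th2 = 0.0
        thV = 0.0
        last = big
        for t in range(n_steps):
            if use_fixed:
                iE += w_fixed[i, t] * weight
            elif np.random.random() < p_spike[t]:
                iE += weight
            if use_bg:
                iE += wE_bg * np.random.poisson(lam_E)
                iI += wI_bg * np.random.poisson(lam_I)
            if t - last >= ref_steps and V >= omega + th1 + th2 + thV:
                if t >= equil_steps:
                    counts[t - equil_steps] += 1
                th1 += alpha1
                th2 += alpha2
                last = t
            Vp = V
            V = E_L + (V - E_L) * pm + iE * pVE + iI * pVI
            thV = thV * pv + beta * (Vp - E_L) * (1.0 - pv)
            th1 *= p1
            th2 *= p2
            iE *= pe
            iI *= pi
    return 0
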