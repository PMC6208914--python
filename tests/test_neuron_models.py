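"""Simulator correctness: oracle equivalence, resting states, thresholds,
refractoriness, state carry-over, noise generation, determinism."""

import numpy as np
import pytest

import lnrate as ln
from lnrate.neuron_models import (ModelSpec, SimulationConfig,
                                  compute_w_theta_amat, gaussian_noise_current,
                                  population_counts, NOISE_PRESETS)
from conftest import amat_psp_analytic, izh_euler_oracle


def _rest_state(params):
    """Stable fixed point (v*, u* = b v*) of the Izhikevich dynamics."""
    A, B, C = 0.04, 5.0 - params.b, 140.0 + params.I_ext
    disc = B * B - 4 * A * C
    v = (-B - np.sqrt(disc)) / (2 * A)
    return v, params.b * v


class TestIzhikevich:
    def test_bit_identical_to_euler_oracle(self, rng):
        """Ten random parameter/input draws reproduce the direct Euler loop
        bit for bit (spike steps and final state)."""
        for _ in range(10):
            a = rng.uniform(0.01, 0.2)
            b = rng.uniform(0.15, 0.26)
            c = rng.uniform(-65.0, -50.0)
            d = rng.uniform(0.0, 8.0)
            p = ln.IzhikevichParams(a=a, b=b, c=c, d=d, xi=1.0)
            n = 5000
            w_in = np.zeros(n)
            idx = rng.choice(n, size=40, replace=False)
            w_in[idx] = rng.uniform(0.0, 20.0, size=40)
            I_in = rng.uniform(-2.0, 10.0, size=n)
            v0, u0 = -70.0, b * -70.0
            cfg = SimulationConfig(T=n * 0.1, equilibration=0.0)
            train, trace = ln.simulate_izhikevich(
                p, [(i * 0.1, w_in[i]) for i in idx], I_in, None, cfg,
                initial_state=(v0, u0))
            spikes, v, u = izh_euler_oracle(a, b, c, d, 30.0, 0.1, 1,
                                            w_in, I_in, v0, u0)
            assert np.array_equal(np.round(train.times / 0.1).astype(int),
                                  spikes)
            assert trace.final_state["v"] == v
            assert trace.final_state["u"] == u

    def test_rest_is_stable(self, quick_config):
        """Variant A at (v, u) = (-70, b*-70) is a fixed point: no spikes."""
        p = ln.izhikevich_params("A")
        train, _ = ln.simulate_izhikevich(p, [], None, None, quick_config,
                                          initial_state=(-70.0, -14.0))
        assert train.n_spikes == 0

    @pytest.mark.parametrize("variant", ["A", "B", "J"])
    def test_single_spike_threshold_matches_xi(self, variant, quick_config):
        """The smallest single-spike weight that triggers spiking from rest
        lies within 2% of the tabulated weight factor xi; a tenth of xi
        never does."""
        p = ln.izhikevich_params(variant)
        rest = _rest_state(p)

        def n_spikes(w):
            train, _ = ln.simulate_izhikevich(p, [(0.0, w)], None, None,
                                              quick_config,
                                              initial_state=rest)
            return train.n_spikes

        assert n_spikes(1.02 * p.xi) >= 1
        assert n_spikes(0.1 * p.xi) == 0
        lo, hi = 0.1 * p.xi, 1.5 * p.xi
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if n_spikes(mid):
                hi = mid
            else:
                lo = mid
        assert hi == pytest.approx(p.xi, rel=0.02)

    def test_substepping_changes_trajectory_slightly(self, quick_config):
        p = ln.izhikevich_params("A")
        cfg2 = SimulationConfig(T=1000.0, equilibration=0.0, n_substeps=2)
        t1, tr1 = ln.simulate_izhikevich(p, [(0.0, 20.0)], 5.0, None,
                                         quick_config, initial_state=(-70.0, -14.0))
        t2, tr2 = ln.simulate_izhikevich(p, [(0.0, 20.0)], 5.0, None, cfg2,
                                         initial_state=(-70.0, -14.0))
        assert t1.n_spikes > 0 and t2.n_spikes > 0
        assert tr1.final_state["v"] != tr2.final_state["v"]

    def test_divergence_raises_with_step_time(self, quick_config):
        p = ln.IzhikevichParams(a=0.02, b=0.2, c=-65, d=6, xi=1.0,
                                V_th=1e300)  # unreachable cut -> runaway
        with pytest.raises(FloatingPointError, match="ms"):
            ln.simulate_izhikevich(p, [(0.0, 30.0)], 10.0, None, quick_config,
                                   initial_state=(-70.0, -14.0))

    def test_split_run_conserves_spikes(self):
        """Splitting a deterministic run in two with carried state yields
        the same total spike count."""
        p = ln.izhikevich_params("C")
        full = SimulationConfig(T=2000.0, equilibration=0.0)
        half = SimulationConfig(T=1000.0, equilibration=0.0)
        tr_full, _ = ln.simulate_izhikevich(p, [], 8.0, None, full,
                                            initial_state=(-70.0, -14.0))
        tr1, st1 = ln.simulate_izhikevich(p, [], 8.0, None, half,
                                          initial_state=(-70.0, -14.0))
        tr2, _ = ln.simulate_izhikevich(
            p, [], 8.0, None, half,
            initial_state=(st1.final_state["v"], st1.final_state["u"]))
        assert tr1.n_spikes + tr2.n_spikes == tr_full.n_spikes


class TestAMAT:
    def test_rest_is_stable(self, quick_config):
        p = ln.amat_params("A")
        cfg = SimulationConfig(T=1000.0, equilibration=0.0,
                               record_voltage=True)
        train, trace = ln.simulate_amat(p, [], None, None, cfg,
                                        initial_state={"V": -70.0})
        assert train.n_spikes == 0
        assert np.all(trace.channels["V"] == -70.0)

    def test_psp_matches_closed_form(self):
        """beta=0, one 200 pA spike from rest: the voltage deviation equals
        the analytic double-exponential PSP at every grid point (<=1e-6 mV);
        exact integration has no truncation error."""
        p = ln.amat_params("A")  # beta = 0
        cfg = SimulationConfig(T=100.0, equilibration=0.0,
                               record_voltage=True)
        t_spk = 10.0
        _, trace = ln.simulate_amat(p, [(t_spk, 200.0)], None, None, cfg,
                                    initial_state={"V": p.E_L})
        t = trace.time
        v = trace.channels["V"]
        expected = np.where(
            t >= t_spk,
            p.E_L + amat_psp_analytic(t - t_spk, 200.0, p.tau_syn_E,
                                      p.tau_m, p.C_m),
            p.E_L)
        assert np.max(np.abs(v - expected)) <= 1e-6

    def test_subthreshold_superposition(self, rng):
        """beta=0 subthreshold trajectories superimpose linearly: an
        arbitrary E/I spike sequence matches the analytic sum (<=1e-6 mV)."""
        p = ln.amat_params("A")
        cfg = SimulationConfig(T=200.0, equilibration=0.0,
                               record_voltage=True)
        events = [(float(rng.integers(0, 1500)) * 0.1,
                   float(rng.uniform(-150, 150))) for _ in range(12)]
        _, trace = ln.simulate_amat(p, events, None, None, cfg,
                                    initial_state={"V": p.E_L})
        t = trace.time
        expected = np.full_like(t, p.E_L)
        for te, w in events:
            tau = p.tau_syn_E if w >= 0 else p.tau_syn_I
            m = t >= te
            expected[m] += amat_psp_analytic(t[m] - te, w, tau, p.tau_m,
                                             p.C_m)
        assert np.max(np.abs(trace.channels["V"] - expected)) <= 1e-6

    def test_beta_zero_reduces_to_plain_mat_threshold(self):
        """With beta=0 the recorded threshold is exactly omega plus the two
        spike-triggered exponentials."""
        p = ln.amat_params("F")  # alpha1=10, alpha2=1, beta=0
        cfg = SimulationConfig(T=500.0, equilibration=0.0,
                               record_voltage=True)
        train, trace = ln.simulate_amat(
            p, [(i * 2.0, 400.0) for i in range(200)], None, None, cfg,
            initial_state={"V": p.E_L})
        assert train.n_spikes > 0
        th = trace.channels["theta"]
        expected = np.full_like(trace.time, p.omega)
        for ts in train.times:
            m = trace.time > ts  # components jump just after the spike bin
            expected[m] += (p.alpha1 * np.exp(-(trace.time[m] - ts) / p.tau_1)
                            + p.alpha2 * np.exp(-(trace.time[m] - ts) / p.tau_2))
        assert np.max(np.abs(th - expected)) <= 1e-9

    def test_isi_at_least_tau_ref(self):
        p = ln.amat_params("A")
        cfg = SimulationConfig(T=2000.0, equilibration=0.0)
        train, _ = ln.simulate_amat(
            p, [(i * 0.5, 600.0) for i in range(4000)], None, None, cfg,
            initial_state={"V": p.E_L})
        assert train.n_spikes > 100
        assert np.all(train.isi() >= p.tau_ref - 1e-9)

    def test_split_run_conserves_spikes(self):
        p = ln.amat_params("A")
        events = [(i * 0.7, 500.0) for i in range(2800)]
        full = SimulationConfig(T=2000.0, equilibration=0.0)
        half = SimulationConfig(T=1000.0, equilibration=0.0)
        tr_full, _ = ln.simulate_amat(p, events, None, None, full,
                                      initial_state={"V": p.E_L})
        ev1 = [(t, w) for t, w in events if t < 1000.0]
        ev2 = [(t - 1000.0, w) for t, w in events if t >= 1000.0]
        tr1, st1 = ln.simulate_amat(p, ev1, None, None, half,
                                    initial_state={"V": p.E_L})
        tr2, _ = ln.simulate_amat(p, ev2, None, None, half,
                                  initial_state=st1.final_state)
        assert tr1.n_spikes + tr2.n_spikes == tr_full.n_spikes


class TestWTheta:
    def test_matches_bisection_oracle(self):
        """Closed-form w_theta agrees with a simulate-and-bisect oracle."""
        p = ln.amat_params("A")
        cfg = SimulationConfig(T=50.0, equilibration=0.0,
                               record_voltage=True)

        def crosses(w):
            _, trace = ln.simulate_amat(p, [(0.0, w)], None, None, cfg,
                                        initial_state={"V": p.E_L})
            return trace.channels["V"].max() >= p.omega

        lo, hi = 100.0, 5000.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if crosses(mid):
                hi = mid
            else:
                lo = mid
        assert compute_w_theta_amat(p) == pytest.approx(hi, rel=1e-3)

    def test_value_and_weight_sweep_coverage(self):
        """w_theta ~ 1.29e3 pA, so the 100-900 pA sweep spans ~8-70% of it."""
        w_theta = compute_w_theta_amat(ln.amat_params("A"))
        assert w_theta == pytest.approx(1.29e3, rel=0.01)
        assert 0.05 < 100.0 / w_theta < 0.10
        assert 0.65 < 900.0 / w_theta < 0.75

    def test_linear_in_threshold_gap(self):
        p = ln.amat_params("A")
        import dataclasses
        p2 = dataclasses.replace(p, omega=p.E_L + 2 * (p.omega - p.E_L))
        assert compute_w_theta_amat(p2) == pytest.approx(
            2 * compute_w_theta_amat(p), rel=1e-12)

    def test_identical_across_variants(self):
        vals = {compute_w_theta_amat(ln.amat_params(v))
                for v in ln.list_variants("amat")}
        assert len(vals) == 1

    def test_invalid_gap_raises(self):
        import dataclasses
        p = dataclasses.replace(ln.amat_params("A"), omega=-75.0)
        with pytest.raises(ValueError):
            compute_w_theta_amat(p)


class TestNoiseAndPresets:
    def test_sigma_zero_is_constant(self):
        tr = gaussian_noise_current(-0.1, 0.0, 0.1, 100.0, seed=1)
        assert np.all(tr == -0.1)

    def test_moments(self):
        tr = gaussian_noise_current(0.0, 0.1, 0.1, 1e5, seed=2)
        assert tr.size == 10 ** 6
        assert abs(tr.mean()) < 4 * 0.1 / np.sqrt(tr.size)
        assert tr.std() == pytest.approx(0.1, rel=0.01)

    def test_regime_presets(self):
        assert NOISE_PRESETS["none"]["izhikevich"] == (0.0, 0.0)
        assert NOISE_PRESETS["balanced"]["izhikevich"] == (0.0, 0.1)
        assert NOISE_PRESETS["balanced"]["amat"] == (0.0, 100.0)
        assert NOISE_PRESETS["biased"]["izhikevich"] == (-0.1, 0.2)
        assert NOISE_PRESETS["biased"]["amat"] == (-100.0, 200.0)

    def test_parameter_tables(self):
        assert len(ln.list_variants("izhikevich")) == 14
        assert len(ln.list_variants("amat")) == 18
        for v in ("L", "R"):
            with pytest.raises(KeyError):
                ln.amat_params(v)
        a = ln.izhikevich_params("A")
        assert (a.a, a.b, a.c, a.d, a.xi) == (0.02, 0.2, -65, 6, 15.1)
        f = ln.amat_params("F")
        assert (f.alpha1, f.alpha2, f.beta) == (10, 1, 0)
        assert (f.E_L, f.omega, f.C_m, f.tau_m) == (-70.0, -65.0, 200.0, 10.0)
        assert (f.tau_1, f.tau_2, f.tau_V, f.tau_ref) == (10.0, 200.0, 5.0, 2.0)
        assert (f.tau_syn_E, f.tau_syn_I) == (1.0, 3.0)


class TestPopulations:
    @pytest.mark.parametrize("model_class,w", [("izhikevich", 0.6),
                                               ("amat", 500.0)])
    def test_same_seed_same_output(self, model_class, w):
        spec = ModelSpec(model_class, "A")
        kw = dict(noise="balanced", n=8, T=500.0, equilibration=100.0)
        c1 = population_counts(spec, 300.0, w, seed=7, **kw)
        c2 = population_counts(spec, 300.0, w, seed=7, **kw)
        c3 = population_counts(spec, 300.0, w, seed=8, **kw)
        assert np.array_equal(c1, c2)
        assert not np.array_equal(c1, c3)

    def test_rate_too_high_rejected(self):
        spec = ModelSpec("amat", "A")
        with pytest.raises(ValueError, match="rate too high"):
            population_counts(spec, 20000.0, 100.0, n=1, T=100.0)
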