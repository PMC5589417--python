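"""Unit and property tests for the ring-attractor integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silentwm.network import (NetworkParams, NetworkState, RingNetwork, gain,
                              connectivity_kernel, kernel_matrix,
                              preferred_angles, run_network, wrap_angle)
from silentwm.protocol import build_schedule


class TestGain:
    def test_value_at_zero(self):
        assert gain(0.0, 1.5) == pytest.approx(1.5 * np.log(2.0))

    def test_threshold_linear_limits(self):
        assert gain(500.0, 1.5) - 500.0 == pytest.approx(0.0, abs=1e-9)
        assert gain(-500.0, 1.5) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_and_nonnegative(self):
        h = np.linspace(-50, 50, 1001)
        r = gain(h, 1.5)
        assert (r >= 0).all()
        assert (np.diff(r) >= 0).all()

    def test_rejects_nonfinite_and_bad_alpha(self):
        with pytest.raises(ValueError):
            gain(np.nan)
        with pytest.raises(ValueError):
            gain(1.0, alpha=0.0)


class TestKernel:
    def test_peak_value(self, default_params):
        # J1*cos(0) - J0 with the published amplitudes
        assert connectivity_kernel(0.3, 0.3, default_params) == pytest.approx(11.0)

    def test_uniform_floor_outside_cutoff(self, default_params):
        # B*delta = pi lies outside arccos(-J0/J1) ~ 1.654 rad
        d = np.pi / default_params.B
        assert connectivity_kernel(d, 0.0, default_params) == pytest.approx(-1.0)

    def test_symmetry_and_translation_invariance(self, default_params):
        rng = np.random.default_rng(0)
        a, b, shift = rng.uniform(-np.pi, np.pi, size=(3, 25))
        k_ab = connectivity_kernel(a, b, default_params)
        np.testing.assert_allclose(k_ab, connectivity_kernel(b, a, default_params))
        np.testing.assert_allclose(
            k_ab,
            connectivity_kernel(wrap_angle(a + shift), wrap_angle(b + shift),
                                default_params), atol=1e-12)

    def test_undefined_cutoff_raises(self):
        p = NetworkParams(J1=2.0, J0=1.0)
        bad = NetworkParams(J1=2.0, J0=1.9)
        assert connectivity_kernel(0.0, 0.0, p) == pytest.approx(1.0)
        object.__setattr__(bad, "J1", 1.0)  # force J0/J1 > 1 past validation
        with pytest.raises(ValueError):
            connectivity_kernel(0.0, 0.0, bad)


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        dict(n_neurons=2), dict(dt=0.1), dict(U=0.0), dict(U=1.5),
        dict(alpha=-1.0), dict(J1=1.0, J0=2.0), dict(tau_f=-1.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkParams(**kwargs)


class TestStep:
    def test_stp_fixed_point_without_firing(self):
        """u = U and x = 1 are stationary when the rate is (numerically) zero."""
        p = NetworkParams(I_b=-60.0)  # gain(I_b) == 0 to double precision
        net = RingNetwork(p)
        state = net.initial_state()
        new = net.step(state, np.zeros(p.n_neurons))
        np.testing.assert_allclose(new.u, p.U, atol=1e-12)
        np.testing.assert_allclose(new.x, 1.0, atol=1e-12)

    def test_rest_state_drift_negligible_in_silent_gain_regime(self):
        """With currents so negative that all rates vanish (and the
        inhibitory pool decoupled), h_E parked at I_b stays there."""
        p = NetworkParams(I_b=-60.0, J_EI=0.0)
        net = RingNetwork(p)
        state = net.initial_state()
        for _ in range(200):
            state = net.step(state, np.zeros(p.n_neurons))
        assert np.abs(state.h_E - p.I_b).max() < 1e-6 * abs(p.I_b)

    def test_divergence_names_component(self):
        p = NetworkParams()
        net = RingNetwork(p)
        state = net.initial_state()
        state.h_E[:] = 1e308
        with pytest.raises(FloatingPointError, match="h_E"):
            net.step(state, np.zeros(p.n_neurons))


class TestRun:
    def test_zero_amplitude_schedule_stays_at_baseline(self, tame_params):
        sched = build_schedule(0.0, A_target=0.0, A_mask=0.0, A_recall=0.0,
                               delay=0.5)
        tr = RingNetwork(tame_params).run(sched, noise=False, decimate=10)
        # baseline self-consistently settles below the uncoupled gain(I_b)
        assert tr.raster.max() < 2 * gain(tame_params.I_b, tame_params.alpha)

    def test_same_seed_reproduces_trace(self, default_params):
        sched = build_schedule(0.3, delay=0.3)
        a = RingNetwork(default_params).run(sched, seed=5, decimate=8)
        b = RingNetwork(default_params).run(sched, seed=5, decimate=8)
        np.testing.assert_array_equal(a.raster, b.raster)

    def test_target_only_schedule_forms_bump_at_target(self, default_params):
        from silentwm.protocol import population_vector_readout
        sched = build_schedule(0.8, A_mask=0.0, A_recall=0.0, delay=1.0)
        tr = RingNetwork(default_params).run(sched, noise=False, decimate=4)
        ro = population_vector_readout(tr, window=(0.9, 1.2))
        assert ro.valid
        spacing = 2 * np.pi / default_params.n_neurons
        assert abs(wrap_angle(ro.angle - 0.8)) < spacing

    def test_translation_equivariance(self, default_params):
        """Shifting the target by k neuron spacings rolls the raster by k."""
        k = 17
        spacing = 2 * np.pi / default_params.n_neurons
        net = RingNetwork(default_params)
        a = net.run(build_schedule(0.0, A_mask=50.0, delay=1.0),
                    noise=False, decimate=10)
        b = net.run(build_schedule(wrap_angle(k * spacing), A_mask=50.0,
                                   delay=1.0), noise=False, decimate=10)
        np.testing.assert_allclose(np.roll(a.raster, k, axis=1), b.raster,
                                   atol=1e-6 * max(1.0, a.raster.max()))

    def test_stp_bounds_on_trial(self, silent_trace):
        _, tr = silent_trace
        p = NetworkParams()
        eps = 1e-9
        assert tr.u.min() >= p.U - eps and tr.u.max() <= 1.0 + eps
        assert tr.x.min() >= -eps and tr.x.max() <= 1.0 + eps

    def test_frozen_stp_delay_is_stationary(self, default_params):
        """With facilitation/depression pinned at baseline there is no
        synaptic trace, hence no delay reactivation."""
        class FrozenSTP(RingNetwork):
            def step(self, state, ext, draws=None, stim=False,
                     mode="continuous"):
                out = super().step(state, ext, draws, stim, mode)
                out.u[...] = self.params.U
                out.x[...] = 1.0
                return out

        sched = build_schedule(0.0, A_mask=50.0)
        tr = FrozenSTP(default_params).run(sched, noise=False, decimate=10)
        lo, hi = sched.delay_window
        win = (tr.times >= lo) & (tr.times <= hi)
        assert tr.raster[win].max() < 5.0  # baseline, no bump reignition


class TestPreferredAngles:
    def test_uniform_spacing_and_range(self):
        th = preferred_angles(40)
        assert th[0] == pytest.approx(-np.pi)
        assert np.allclose(np.diff(th), 2 * np.pi / 40)
        assert th[-1] < np.pi


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(-100, 100), st.floats(-100, 100))
def test_wrap_angle_identity_and_range(a, b):
    w = wrap_angle(a - b)
    assert -np.pi < w <= np.pi + 1e-12
    assert np.cos(w) == pytest.approx(np.cos(a - b), abs=1e-9)
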