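"""Core model: gain function, kernels, currents, derivatives, integration."""

import numpy as np
import pytest

from shepnet._integrate import StepSizeUnderflow, integrate_adaptive
from shepnet.dynamics import (
    KernelSet,
    NetworkParams,
    NetworkState,
    build_kernels,
    derivatives,
    sigmoid,
    simulate,
    synaptic_currents,
)
from shepnet.grids import TonotopicGrid
from shepnet.stimuli import DriveEvent, InputDrive, ToneEvent, make_shepard_drive, make_tritone_trial

from _oracles import direct_conv


class TestSigmoid:
    def test_zero_at_zero(self):
        assert sigmoid(0.0, 0.5, 0.1) == 0.0
        assert sigmoid(0.0, 0.3, 0.2) == 0.0

    def test_closed_form_values(self):
        # s0*(1/(1+exp((theta-x)/k)) - x0), x0 = 1/(1+exp(theta/k))
        assert sigmoid(0.5, 0.5, 0.1) == pytest.approx(0.4966310, abs=1e-6)
        assert sigmoid(0.3, 0.3, 0.2) == pytest.approx(0.3884347, abs=1e-6)

    def test_saturation_and_monotonicity(self):
        x = np.linspace(0.0, 3.0, 200)
        v = sigmoid(x, 0.5, 0.1)
        assert np.all(np.diff(v) > 0)
        assert sigmoid(50.0, 0.5, 0.1) == pytest.approx(1.0, abs=1e-9)

    def test_floor_keeps_rates_nonnegative(self):
        assert sigmoid(-5.0, 0.5, 0.1) == 0.0
        assert sigmoid(-5.0, 0.5, 0.1, floor=False) < 0.0

    def test_invalid_slope(self):
        with pytest.raises(ValueError):
            sigmoid(0.1, 0.5, 0.0)


@pytest.mark.parametrize("regime", ["narrow", "broad"])
@pytest.mark.parametrize("topology", ["ring", "line"])
class TestKernels:
    def _kernels(self, regime, topology):
        p = NetworkParams.broad() if regime == "broad" else NetworkParams()
        g = TonotopicGrid.ring() if topology == "ring" else TonotopicGrid.line(4.0)
        return build_kernels(p, g), g

    def test_unit_area(self, regime, topology):
        ks, g = self._kernels(regime, topology)
        for name in ("omega_ee", "omega_ei", "omega_up", "omega_down"):
            assert getattr(ks, name).sum() * g.dx == pytest.approx(1.0, abs=1e-12)

    def test_one_sided_support(self, regime, topology):
        ks, g = self._kernels(regime, topology)
        d = ks.displacements
        interior = np.abs(np.abs(d) - g.extent / 2.0) > 1e-12  # exclude ring antipode
        assert np.all(ks.omega_up[(d > 1e-12) & interior] == 0.0)
        assert np.all(ks.omega_down[(d < -1e-12) & interior] == 0.0)
        # +0.1 oct is strictly inside the forbidden side
        i = int(np.argmin(np.abs(d - 0.1)))
        assert ks.omega_up[i] == 0.0

    def test_mirror_symmetry(self, regime, topology):
        # omega_up(-x) == omega_down(x) sample by sample
        ks, g = self._kernels(regime, topology)
        if topology == "ring":
            m = np.arange(g.n)
            mirrored = ks.omega_down[(g.n - m) % g.n]
        else:
            mirrored = ks.omega_down[::-1]
        assert np.allclose(ks.omega_up, mirrored, atol=1e-15)


class TestConvolution:
    @pytest.mark.parametrize("topology", ["ring", "line"])
    def test_fft_matches_direct_sum(self, topology):
        g = TonotopicGrid.ring() if topology == "ring" else TonotopicGrid.line(3.0)
        ks = build_kernels(NetworkParams(), g)
        rng = np.random.default_rng(42)
        field = rng.uniform(0.0, 1.0, g.n)
        for kern, conv in (
            (ks.omega_ee, ks.conv_ee),
            (ks.omega_ei, ks.conv_ei),
            (ks.omega_up, ks.conv_up),
            (ks.omega_down, ks.conv_down),
        ):
            assert np.allclose(conv(field), direct_conv(kern, field, g), atol=1e-12)

    def test_updown_stack_consistent(self, ring):
        ks = build_kernels(NetworkParams(), ring)
        field = np.sin(np.linspace(0, 2 * np.pi, ring.n)) ** 2
        both = ks.conv_updown(field)
        assert np.allclose(both[0], ks.conv_up(field), atol=1e-14)
        assert np.allclose(both[1], ks.conv_down(field), atol=1e-14)


class TestSynapticCurrents:
    def test_zero_state_zero_currents(self, ring, params):
        ks = build_kernels(params, ring)
        h = synaptic_currents(NetworkState.zeros(ring), ks, params)
        for v in h.values():
            assert np.all(v == 0.0)

    def test_no_facilitation_factor(self, ring, params):
        ks = build_kernels(params, ring)
        state = NetworkState.zeros(ring)
        state.r_I = np.exp(-((ring.x - 0.5) ** 2) / 0.01)
        h = synaptic_currents(state, ks, params)
        expected = params.a_ie * direct_conv(ks.omega_up, state.r_I, ring)
        assert np.allclose(h["h_ie_up"], expected, atol=1e-12)

    def test_mirror_bump_symmetry(self, ring, params):
        # symmetric inhibitory bump at x*: h_up at x*-d equals h_down at x*+d
        ks = build_kernels(params, ring)
        state = NetworkState.zeros(ring)
        c = ring.n // 2
        state.r_I = np.exp(-(ring.distance(ring.x, ring.x[c]) ** 2) / 0.02)
        h = synaptic_currents(state, ks, params)
        for d in (5, 13, 30):
            assert h["h_ie_up"][c - d] == pytest.approx(h["h_ie_down"][c + d], rel=1e-10)

    def test_facilitation_acts_presynaptically(self, ring, params):
        # facilitating only at the bump boosts currents by the same profile-weighted factor
        ks = build_kernels(params, ring)
        state = NetworkState.zeros(ring)
        state.r_I[40] = 1.0
        base = synaptic_currents(state, ks, params)
        state.F[40] = 0.5  # F elsewhere irrelevant: r_I = 0 there
        state.F[10] = 1.0
        boosted = synaptic_currents(state, ks, params)
        factor = 1.0 + params.gamma_f * 0.5
        assert np.allclose(boosted["h_ie_up"], factor * base["h_ie_up"], atol=1e-14)

    def test_grid_mismatch_rejected(self, ring, params):
        ks = build_kernels(params, ring)
        with pytest.raises(ValueError):
            synaptic_currents(np.zeros((4, ring.n + 1)), ks, params)


class TestDerivatives:
    def test_rest_is_fixed_point(self, ring, params):
        ks = build_kernels(params, ring)
        dy = derivatives(NetworkState.zeros(ring), np.zeros(ring.n), params, ks)
        assert np.all(dy == 0.0)

    def test_facilitation_decay_at_cap(self, ring, params):
        ks = build_kernels(params, ring)
        state = NetworkState.zeros(ring)
        state.F[:] = 1.0
        dy = derivatives(state, np.zeros(ring.n), params, ks)
        assert np.allclose(dy[3], -1.0 / params.tau_fd)

    def test_facilitation_rise(self, ring, params):
        ks = build_kernels(params, ring)
        state = NetworkState.zeros(ring)
        state.r_I[:] = 0.5
        dy = derivatives(state, np.zeros(ring.n), params, ks)
        assert np.allclose(dy[3], 0.5 / params.tau_fr)


class TestIntegration:
    def test_zero_drive_stays_at_rest(self, ring, params):
        drive = InputDrive(ring, [DriveEvent(np.zeros((1, ring.n)), 0.0, 50.0)])
        trace = simulate(drive, params, t_span=(0.0, 120.0))
        assert np.all(trace.y == 0.0)

    def test_facilitation_fixed_point_closed_form(self):
        # constant r_I = c drives F toward c*tau_fd / (tau_fr + c*tau_fd)
        c, tau_fr, tau_fd = 0.5, 100.0, 2000.0
        f_end = integrate_adaptive(
            lambda t, f: -f / tau_fd + c * (1.0 - f) / tau_fr,
            (0.0, 20000.0),
            np.zeros(1),
        )
        assert f_end[0] == pytest.approx(c * tau_fd / (tau_fr + c * tau_fd), abs=1e-5)

    def test_rates_and_facilitation_bounded(self, biased_trial):
        trace, _, _ = biased_trial
        assert trace.y.min() >= 0.0
        assert trace.r_up.max() <= 1.0 and trace.r_down.max() <= 1.0
        assert trace.r_I.max() <= 1.0 and trace.F.max() <= 1.0

    def test_translation_equivariance_on_ring(self, ring, params):
        # shifting the stimulus by 3 st (25 grid points) shifts all fields
        traces = []
        for t1 in (0.0, 3.0):
            seq = make_tritone_trial(t1, 0, "up")
            traces.append(simulate(InputDrive.from_sequence(seq, ring), params))
        for t_probe in (150.0, 250.0):
            a = traces[0].state_at(t_probe).to_array()
            b = traces[1].state_at(t_probe).to_array()
            assert np.allclose(np.roll(a, 25, axis=-1), b, atol=1e-7)

    def test_mirror_swaps_populations(self, ring, params):
        # reflecting the stimulus about 0 st swaps r_up and (reflected) r_down
        from shepnet.stimuli import ToneSequence

        pair = ToneSequence((ToneEvent(0.0, 0.0, 100.0), ToneEvent(3.0, 150.0, 100.0)))
        mirrored = ToneSequence((ToneEvent(0.0, 0.0, 100.0), ToneEvent(9.0, 150.0, 100.0)))
        t_a = simulate(InputDrive.from_sequence(pair, ring), params)
        t_b = simulate(InputDrive.from_sequence(mirrored, ring), params)
        a = t_a.state_at(250.0).to_array()[0]
        b = t_b.state_at(250.0).to_array()[0]
        flip = np.concatenate(([0], np.arange(ring.n - 1, 0, -1)))  # x -> -x on grid
        assert np.allclose(a[0], b[1][..., flip], atol=1e-7)
        assert np.allclose(a[2], b[2][..., flip], atol=1e-7)

    def test_underflow_raises_with_timestamp(self, ring, params):
        seq = make_tritone_trial(0.0, 0, "up")
        drive = InputDrive.from_sequence(seq, ring)
        with pytest.raises(StepSizeUnderflow, match="t ="):
            simulate(drive, params, rtol=1e-14, atol=1e-14, min_step=0.5, t_span=(0.0, 50.0))

    def test_trace_exports(self, biased_trial, tmp_path):
        trace, _, _ = biased_trial
        df = trace.to_dataframe()
        assert set(df.columns) == {"t_ms", "x_st", "r_up", "r_down", "r_I", "F"}
        assert len(df) == len(trace.t) * trace.grid.n
        trace.save_npz(tmp_path / "trace.npz")
        back = np.load(tmp_path / "trace.npz")
        assert np.array_equal(back["y"], trace.y)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(tau_e=-1.0)
        with pytest.raises(ValueError):
            NetworkParams(sigma_ei=0.0)
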