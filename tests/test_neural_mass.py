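"""Simulator unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from nmgc import neural_mass as nm
from nmgc.spectra import band_peak, welch_psd


class TestSigmoid:
    P = nm.SigmoidParams(e0=2.5, r=0.56, v0=6.0)

    def test_center_returns_half_max(self):
        assert nm.sigmoid(6.0, self.P) == pytest.approx(2.5)

    def test_asymptotes(self):
        assert nm.sigmoid(1e3, self.P) == pytest.approx(5.0)
        assert nm.sigmoid(-1e3, self.P) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self):
        # 2*2.5 / (1 + exp(0.56*6)) at v = 0
        expected = 5.0 / (1.0 + np.exp(3.36))
        assert nm.sigmoid(0.0, self.P) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1678, abs=5e-4)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounded_and_increasing(self, v1, v2):
        z1, z2 = nm.sigmoid(v1, self.P), nm.sigmoid(v2, self.P)
        assert 0 < z1 < 2 * self.P.e0
        if v1 + 1e-6 < v2:  # strictness needs a resolvable gap in float64
            assert z1 < z2

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            nm.SigmoidParams(e0=-1.0)


class TestPresets:
    def test_presets_are_constants(self):
        assert nm.preset("alpha") == nm.preset("alpha")

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError, match="unknown rhythm"):
            nm.preset("delta")

    def test_overrides(self):
        assert nm.preset("theta", m_p=800.0).m_p == 800.0

    @pytest.mark.parametrize("band", ["theta", "alpha", "beta", "gamma"])
    def test_isolated_psd_peak_in_band(self, band, preset_sims):
        """Each preset's isolated 10 s trace peaks inside its nominal band."""
        from nmgc.preprocess import preprocess_sim

        ts = preprocess_sim(preset_sims[band], normalize=False)
        psd = welch_psd(ts.data[:, 0], ts.fs)
        pk = band_peak(psd)
        lo, hi = nm.BANDS[band]
        assert lo <= pk.freq <= hi
        assert pk.band == band
        assert pk.dominant


class TestSimulate:
    def test_seeded_bit_reproducibility(self):
        net = nm.Network(rois=(nm.preset("alpha"),))
        a = nm.simulate(net, duration=1.0, seed=7)
        b = nm.simulate(net, duration=1.0, seed=7)
        assert np.array_equal(a.vp, b.vp)

    def test_batch_matches_single_trial(self):
        """Trials share no RNG state: batched == individually simulated."""
        net = nm.Network(
            rois=(nm.preset("alpha"), nm.preset("beta")),
            connections=(nm.Connection(0, 1, 40.0),),
        )
        batch = nm.simulate_trials(net, duration=1.0, seeds=[3, 4])
        solo = nm.simulate(net, duration=1.0, seed=4)
        assert np.array_equal(batch[1].vp, solo.vp)

    def test_n_samples(self):
        net = nm.Network(rois=(nm.preset("theta"),))
        out = nm.simulate(net, duration=0.5, seed=0)
        assert out.n_samples == round(0.5 / out.dt_raw)
        assert np.isfinite(out.vp).all()

    def test_noise_free_reaches_fixed_point(self):
        roi = nm.preset("alpha", sigma_p=0.0, sigma_f=0.0)
        net = nm.Network(rois=(roi,))
        out = nm.simulate(net, duration=5.0, seed=0)
        tail = out.vp[-2000:, 0]
        assert np.abs(np.diff(tail)).max() < 1e-8

    def test_dt_guard(self):
        net = nm.Network(rois=(nm.preset("gamma"),))
        with pytest.raises(ValueError, match="dt"):
            nm.simulate(net, duration=0.1, dt=1e-3)

    def test_divergence_reported_with_roi_and_time(self):
        # identity rates make the system linear; a mutual excitatory loop
        # with DC gain (G/omega * W)^2 >> 1 grows without bound
        roi = nm.ROIParams(
            sigmoid=nm.SigmoidParams(), kin_exc=nm.SynapseKinetics(3.25, 100.0),
            kin_slow=nm.SynapseKinetics(22.0, 50.0),
            kin_fast=nm.SynapseKinetics(10.0, 500.0),
            C=nm.InternalCoupling(0, 0, 0, 0, 0, 0, 0, 0),
            m_p=1.0, sigma_p=0.0, sigma_f=0.0, rhythm="alpha",
        )
        net = nm.Network(rois=(roi, roi), connections=(
            nm.Connection(0, 1, 5000.0), nm.Connection(1, 0, 5000.0)))
        with pytest.raises(nm.SimulationDiverged, match="ROI"):
            nm.simulate(net, duration=3.0, seed=0, rate_transform="identity")

    def test_linear_synapse_step_response(self):
        """With identity rates and no coupling, v_p follows the analytic
        critically damped second-order step response within O(dt)."""
        kin = nm.SynapseKinetics(G=3.25, omega=100.0)
        roi = nm.ROIParams(
            sigmoid=nm.SigmoidParams(), kin_exc=kin,
            kin_slow=nm.SynapseKinetics(22.0, 50.0),
            kin_fast=nm.SynapseKinetics(10.0, 500.0),
            C=nm.InternalCoupling(0, 0, 0, 0, 0, 0, 0, 0),
            m_p=1.0, m_f=0.0, sigma_p=0.0, sigma_f=0.0, rhythm="alpha",
        )
        net = nm.Network(rois=(roi,))
        dt = 1e-4
        out = nm.simulate(net, duration=0.2, dt=dt, seed=0, rate_transform="identity")
        t = np.arange(out.n_samples) * dt
        G, om = kin.G, kin.omega
        expected = (G / om) * (1.0 - np.exp(-om * t) * (1.0 + om * t))
        assert np.max(np.abs(out.vp[:, 0] - expected)) < 20 * dt

    def test_impulse_response_peak_location(self):
        kin = nm.SynapseKinetics(G=2.0, omega=80.0)
        t = np.linspace(0, 0.2, 10001)
        h = kin.impulse_response(t)
        assert h.min() >= 0
        assert t[np.argmax(h)] == pytest.approx(1.0 / kin.omega, rel=2e-3)


class TestDelays:
    def test_delay_buffer_equals_explicit_shift(self):
        """The connection PSP equals the target's glutamatergic filter applied
        to the explicitly time-shifted source rate trace."""
        net = nm.Network(
            rois=(nm.preset("gamma"), nm.preset("theta")),
            connections=(nm.Connection(0, 1, 30.0, "excitatory", D=0.010),),
        )
        dt = 1e-4
        out = nm.simulate(net, duration=2.0, dt=dt, seed=2, store_psp=True,
                          store_rates=True)
        lag = round(0.010 / dt)
        z_src = out.rates[:, 0]
        # resting source rate primes the pre-connection history
        drive = 30.0 * np.concatenate([np.full(lag, z_src[0]), z_src[:-lag]])
        kin = net.rois[1].kin_exc
        y = dy = 0.0
        ref = np.empty_like(drive)
        for k, u in enumerate(drive):
            ref[k] = y
            acc = kin.G * kin.omega * u - 2 * kin.omega * dy - kin.omega**2 * y
            y += dt * dy
            dy += dt * acc
        assert np.allclose(out.psp[0], ref, atol=1e-10)

    def test_cross_correlation_peaks_near_delay(self):
        """Source rate leads the connection PSP by roughly D plus the synaptic
        rise time 1/omega."""
        D = 0.010
        net = nm.Network(
            rois=(nm.preset("gamma"), nm.preset("theta")),
            connections=(nm.Connection(0, 1, 40.0, "excitatory", D=D),
                         nm.Connection(1, 0, 40.0, "excitatory", D=D)),
        )
        out = nm.simulate(net, duration=6.0, seed=3, store_psp=True, store_rates=True)
        z = out.rates[10000:, 0] - out.rates[10000:, 0].mean()
        y = out.psp[0][10000:] - out.psp[0][10000:].mean()
        max_lag = 600
        lags = np.arange(max_lag)
        cc = np.array([np.dot(z[: len(z) - k], y[k:]) for k in lags])
        best = lags[np.argmax(cc)] * out.dt_raw
        expected = D + 1.0 / net.rois[1].kin_exc.omega
        assert abs(best - expected) < 0.008


class TestPSPSummary:
    def test_zero_weight_gives_zero(self):
        net = nm.Network(
            rois=(nm.preset("alpha"), nm.preset("beta")),
            connections=(nm.Connection(0, 1, 0.0),),
        )
        out = nm.simulate(net, duration=1.5, seed=0, store_psp=True)
        assert nm.postsynaptic_current_summary(out, net.connections[0]) == 0.0

    def test_foreign_connection_rejected(self):
        net = nm.Network(
            rois=(nm.preset("alpha"), nm.preset("beta")),
            connections=(nm.Connection(0, 1, 10.0),),
        )
        out = nm.simulate(net, duration=1.5, seed=0, store_psp=True)
        with pytest.raises(ValueError, match="not part"):
            nm.postsynaptic_current_summary(out, nm.Connection(1, 0, 10.0))

    def test_summary_increases_with_weight(self, gamma_theta_sweep):
        df, _ = gamma_theta_sweep
        means = df.groupby("W")["psp_fwd"].mean()
        assert means.is_monotonic_increasing
        assert means.iloc[0] > 0


class TestNetworkValidation:
    def test_duplicate_connection_rejected(self):
        rois = (nm.preset("alpha"), nm.preset("beta"))
        with pytest.raises(ValueError, match="duplicate"):
            nm.Network(rois=rois, connections=(
                nm.Connection(0, 1, 10.0), nm.Connection(0, 1, 20.0)))

    def test_self_connection_rejected(self):
        with pytest.raises(ValueError):
            nm.Connection(1, 1, 10.0)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            nm.Network(rois=(nm.preset("alpha"),),
                       connections=(nm.Connection(0, 1, 10.0),))

    def test_weight_matrix_convention(self):
        net = nm.Network(
            rois=(nm.preset("alpha"), nm.preset("beta")),
            connections=(nm.Connection(0, 1, 33.0),),
        )
        W = net.weight_matrix()
        assert W[1, 0] == 33.0 and W[0, 1] == 0.0


def test_long_run_stability():
    """All presets stay bounded over a 60 s run with default inputs."""
    net = nm.Network(rois=tuple(nm.preset(b) for b in nm.BANDS))
    out = nm.simulate(net, duration=60.0, seed=5, store_psp=False)
    assert np.isfinite(out.vp).all()
    assert np.abs(out.vp).max() < 200.0
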