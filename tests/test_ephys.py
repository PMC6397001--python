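"""Whole-cell subtraction and I-V fitting; single-channel idealization and nPo."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanocoloc as nc
from nanocoloc import ephys


def _sweep(samples, rate=10000.0, cap=12.0, **kw):
    return ephys.CurrentSweep(
        samples_pa=np.asarray(samples, dtype=float), sample_rate_hz=rate,
        holding_mv=-70.0, test_mv=10.0, capacitance_pf=cap, **kw,
    )


class TestSubtraction:
    def test_identical_sweeps_cancel(self):
        a = _sweep(np.full(100, -50.0))
        assert np.all(ephys.subtract_nifedipine_sensitive(a, a).samples_pa == 0.0)

    def test_plateau_arithmetic(self):
        total = _sweep(np.full(100, -100.0))
        residual = _sweep(np.full(100, -20.0))
        out = ephys.subtract_nifedipine_sensitive(total, residual)
        assert np.all(out.samples_pa == -80.0)

    def test_capacitance_inherited_from_total(self):
        total = _sweep(np.zeros(10), cap=15.0)
        residual = ephys.CurrentSweep(np.zeros(10), 10000.0, -70.0, 10.0, capacitance_pf=99.0)
        assert ephys.subtract_nifedipine_sensitive(total, residual).capacitance_pf == 15.0

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError):
            ephys.subtract_nifedipine_sensitive(_sweep(np.zeros(10)), _sweep(np.zeros(11)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_subtraction_linearity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=50)
        c = rng.normal(size=50)
        out = ephys.subtract_nifedipine_sensitive(_sweep(a + c), _sweep(c))
        assert np.allclose(out.samples_pa, a)


class TestCurrentDensity:
    def test_peak_over_capacitance(self):
        x = np.zeros(1000)
        x[500] = -120.0
        assert ephys.current_density(_sweep(x, cap=12.0)) == pytest.approx(-10.0)

    def test_zero_sweep(self):
        assert ephys.current_density(_sweep(np.zeros(100))) == 0.0

    def test_missing_capacitance_raises(self):
        with pytest.raises(ValueError, match="capacitance"):
            ephys.current_density(_sweep(np.zeros(100), cap=None))

    def test_capacitive_transient_excluded(self):
        # a huge artifact in the first 5 ms of the test window is ignored
        rate = 10000.0
        x = np.zeros(2000)
        x[10] = -500.0   # transient at 1 ms
        x[1000] = -60.0  # true peak
        sweep = _sweep(x, rate=rate, test_window_s=(0.0, 0.2))
        assert ephys.current_density(sweep) == pytest.approx(-5.0)


class TestIVFit:
    def test_exact_recovery_noiseless(self):
        spec = nc.IVCurveSpec(imax_pa_pf=-5.5, vmax_mv=12.0, b_mv=18.0, noise_sd_pa_pf=0.0)
        fit = nc.fit_iv_gaussian(nc.simulate_iv_curve(spec))
        assert abs(fit.vmax_mv - 12.0) < 1e-6
        assert abs(fit.imax_pa_pf + 5.5) < 1e-6
        assert abs(fit.b_mv - 18.0) < 1e-6

    @given(
        st.floats(-12.0, -1.0),
        st.floats(-10.0, 25.0),
        st.floats(10.0, 35.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_recovery_property(self, imax, vmax, b):
        spec = nc.IVCurveSpec(imax_pa_pf=imax, vmax_mv=vmax, b_mv=b, noise_sd_pa_pf=0.0)
        fit = nc.fit_iv_gaussian(nc.simulate_iv_curve(spec))
        assert fit.vmax_mv == pytest.approx(vmax, abs=1e-5)
        assert fit.b_mv == pytest.approx(b, abs=1e-4)

    def test_noisy_recovery_over_seeds(self):
        vmaxes = [
            nc.fit_iv_gaussian(nc.simulate_iv_curve(nc.IVCurveSpec(vmax_mv=14.9, seed=s))).vmax_mv
            for s in range(20)
        ]
        assert abs(np.mean(vmaxes) - 14.9) < 1.0

    def test_junction_correction_is_a_pure_shift(self):
        v = np.arange(-60.0, 61.0, 10.0)
        assert np.allclose(ephys.correct_junction_potential(v), v - 10.0)


class TestGaussianFilter:
    def test_constant_unchanged(self):
        x = np.full(1000, 3.7)
        assert np.allclose(ephys.gaussian_filter_trace(x, 10000.0, 500.0), 3.7)

    def test_minus_3db_at_cutoff(self):
        # a sinusoid at the cutoff frequency comes out at 1/sqrt(2) amplitude
        rate, f = 50000.0, 500.0
        t = np.arange(0, 1.0, 1 / rate)
        x = np.sin(2 * np.pi * f * t)
        y = ephys.gaussian_filter_trace(x, rate, f)
        ratio = y[5000:-5000].std() / x[5000:-5000].std()
        assert ratio == pytest.approx(1 / np.sqrt(2), abs=0.01)

    def test_noise_variance_reduced(self, rng):
        x = rng.normal(size=20000)
        assert ephys.gaussian_filter_trace(x, 10000.0).var() < x.var()


class TestIdealization:
    def test_flat_trace_no_events(self):
        ideal = ephys.idealize_half_amplitude(np.zeros(1000), -1.0, baseline_pa=0.0)
        assert len(ideal.events) == 0
        assert nc.compute_npo(ideal).npo == 0.0

    def test_square_pulse_open_fraction(self):
        # unitary-amplitude pulse over 40% of the sweep -> one event, nPo 0.40
        x = np.zeros(1000)
        x[300:700] = -1.0
        ideal = ephys.idealize_half_amplitude(x, -1.0, baseline_pa=0.0, sample_rate_hz=10000.0)
        assert len(ideal.events) == 1
        assert ideal.events[0][2] == 1
        assert nc.compute_npo(ideal).npo == pytest.approx(0.40)

    def test_double_opening_is_level_two(self):
        x = np.zeros(1000)
        x[100:300] = -2.0
        ideal = ephys.idealize_half_amplitude(x, -1.0, baseline_pa=0.0)
        assert ideal.events[0][2] == 2

    def test_half_amplitude_threshold_rule(self):
        # deflection of 0.49·|u| stays closed; 0.51·|u| opens
        x = np.zeros(100)
        x[10:20] = -0.49
        x[50:60] = -0.51
        ideal = ephys.idealize_half_amplitude(x, -1.0, baseline_pa=0.0, dead_time_samples=1)
        assert len(ideal.events) == 1
        assert ideal.events[0][0] == pytest.approx(0.005)

    def test_dead_time_drops_short_events(self):
        x = np.zeros(1000)
        x[100] = -1.0  # single-sample blip
        ideal = ephys.idealize_half_amplitude(x, -1.0, baseline_pa=0.0, dead_time_samples=2)
        assert len(ideal.events) == 0

    def test_full_sweep_open_gives_npo_one(self):
        ideal = ephys.idealize_half_amplitude(np.full(1000, -1.0), -1.0, baseline_pa=0.0)
        assert nc.compute_npo(ideal).npo == pytest.approx(1.0)

    def test_offset_invariance_with_baseline_reestimation(self):
        spec = nc.MarkovChannelSpec(seed=17, noise_sd_pa=0.2)
        trace = nc.simulate_single_channel_trace(spec)
        filt = ephys.gaussian_filter_trace(trace.current_pa, spec.sample_rate_hz)
        npo0 = nc.compute_npo(ephys.idealize_half_amplitude(filt, -1.0)).npo
        npo_shifted = nc.compute_npo(ephys.idealize_half_amplitude(filt - 7.3, -1.0)).npo
        assert npo_shifted == pytest.approx(npo0, abs=1e-9)

    def test_po_recovery_bias_below_10_percent_at_snr_5(self):
        # simulate -> filter -> idealize at SNR 5 recovers stationary Po
        spec_kw = dict(open_rate=25.0, close_rate=100.0, unitary_amplitude_pa=-1.0, noise_sd_pa=0.2)
        npos, latents = [], []
        for seed in range(30):
            spec = nc.MarkovChannelSpec(seed=seed, **spec_kw)
            tr = nc.simulate_single_channel_trace(spec)
            filt = ephys.gaussian_filter_trace(tr.current_pa, spec.sample_rate_hz)
            npos.append(nc.compute_npo(ephys.idealize_half_amplitude(filt, -1.0)).npo)
            latents.append(tr.latent_open_fraction)
        bias = abs(np.mean(npos) - 0.2) / 0.2
        assert bias < 0.10
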