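"""Generator-side tests: determinism, conservation, and ground-truth geometry."""

import numpy as np
import pytest
from scipy import stats as sps

import nanocoloc as nc
from nanocoloc.synthetic import PlacementError

from conftest import brute_force_nnd, flood_fill_components


class TestClusterField:
    def test_zero_density_gives_empty_map(self):
        field = nc.generate_cluster_map(nc.ClusterFieldSpec(cluster_density_um2=0.0, seed=1))
        assert field.binary_map.foreground_count() == 0
        assert len(field.centroids) == 0

    def test_cluster_count_matches_flood_fill_oracle(self):
        # 2 µm × 2 µm at 10/µm² must contain exactly 40 objects
        spec = nc.ClusterFieldSpec(
            field_width_nm=2000, field_height_nm=2000, cluster_density_um2=10.0, seed=7
        )
        field = nc.generate_cluster_map(spec)
        comps = flood_fill_components(field.binary_map.pixels)
        assert len(comps) == 40

    def test_foreground_equals_sum_of_cluster_areas(self):
        field = nc.generate_cluster_map(nc.ClusterFieldSpec(seed=11))
        px2 = field.spec.pixel_size_nm**2
        assert field.binary_map.foreground_count() == int(field.centroids["area_nm2"].sum() / px2)

    def test_seed_determinism(self):
        spec = nc.ClusterFieldSpec(field_width_nm=2000, field_height_nm=2000, seed=5)
        a = nc.generate_cluster_map(spec)
        b = nc.generate_cluster_map(spec)
        assert np.array_equal(a.binary_map.pixels, b.binary_map.pixels)
        assert a.centroids.equals(b.centroids)

    def test_impossible_density_raises_placement_error(self):
        spec = nc.ClusterFieldSpec(
            field_width_nm=1000, field_height_nm=1000, cluster_density_um2=3000.0, seed=0
        )
        with pytest.raises(PlacementError):
            nc.generate_cluster_map(spec)


class TestCoupledPair:
    def test_full_coupling_at_fixed_distance(self):
        # coupled_fraction 1, sd ~ 0, mean 50 nm: every query-to-nearest-reference
        # distance is 50 nm up to rasterization error (about one pixel)
        spec = nc.coupled_pair_spec(
            coupled_fraction=1.0,
            coupling_distance_mean_nm=50.0,
            coupling_distance_sd_nm=1e-9,
            density_um2=1.0,
            field_nm=10000.0,
            seed=2,
        )
        pair = nc.generate_coupled_pair(spec)
        d = brute_force_nnd(
            pair.query.centroids[["x_nm", "y_nm"]].to_numpy(),
            pair.reference.centroids[["x_nm", "y_nm"]].to_numpy(),
        )
        assert np.all(np.abs(d - 50.0) <= spec.reference.pixel_size_nm + 1e-9)

    def test_labels_partition_and_coupled_distance_mean(self):
        spec = nc.coupled_pair_spec(seed=3, field_nm=16000.0)
        pair = nc.generate_coupled_pair(spec)
        assert len(pair.coupled) == len(pair.query.centroids)
        d = brute_force_nnd(
            pair.query.centroids[["x_nm", "y_nm"]].to_numpy(),
            pair.reference.centroids[["x_nm", "y_nm"]].to_numpy(),
        )
        coupled_d = d[pair.coupled]
        se = coupled_d.std(ddof=1) / np.sqrt(len(coupled_d))
        # nearest-neighbour distances can only undershoot the planted distance,
        # so compare against the planted mean with a 3 SE band
        assert abs(coupled_d.mean() - spec.coupling_distance_mean_nm) < 3 * se + 2.0

    def test_zero_coupling_indistinguishable_from_random(self):
        # with no coupling the query NND distribution must match that of an
        # independently generated random query field (KS test, alpha = 0.01)
        spec_a = nc.coupled_pair_spec(coupled_fraction=0.0, seed=10, field_nm=16000.0)
        spec_b = nc.coupled_pair_spec(coupled_fraction=0.0, seed=40, field_nm=16000.0)
        ref = nc.generate_coupled_pair(spec_a)
        other = nc.generate_coupled_pair(spec_b)
        ref_xy = ref.reference.centroids[["x_nm", "y_nm"]].to_numpy()
        d1 = brute_force_nnd(ref.query.centroids[["x_nm", "y_nm"]].to_numpy(), ref_xy)
        d2 = brute_force_nnd(other.query.centroids[["x_nm", "y_nm"]].to_numpy(),
                             other.reference.centroids[["x_nm", "y_nm"]].to_numpy())
        assert sps.ks_2samp(d1, d2).pvalue > 0.01


class TestSpotStack:
    def test_zero_emitters_is_background_only(self):
        spec = nc.SpotImageSpec(n_frames=4, emitters=[], background=5.0,
                                field_width_nm=1600, field_height_nm=1600, seed=1)
        stack = nc.render_spot_stack(spec)
        assert stack.shape == (4, 16, 16)
        assert abs(stack.mean() - 5.0) < 3 * np.sqrt(5.0 / stack.size)

    def test_integrated_intensity_matches_photon_count(self):
        n = 2000.0
        spec = nc.SpotImageSpec(
            n_frames=1, emitters=[(800.0, 800.0, n)], background=0.0,
            field_width_nm=1600, field_height_nm=1600, seed=2,
        )
        frame = nc.render_spot_stack(spec)[0]
        assert abs(frame.sum() - n) <= 3 * np.sqrt(n)

    def test_determinism(self):
        spec = nc.SpotImageSpec(n_frames=2, emitters=[(500.0, 700.0, 1500.0)],
                                background=3.0, field_width_nm=1000, field_height_nm=1000, seed=9)
        assert np.array_equal(nc.render_spot_stack(spec), nc.render_spot_stack(spec))


class TestSingleChannel:
    def test_vanishing_open_rate_gives_flat_trace(self):
        spec = nc.MarkovChannelSpec(open_rate=1e-9, close_rate=100.0, noise_sd_pa=0.0, seed=4)
        trace = nc.simulate_single_channel_trace(spec)
        assert trace.open_count.max() == 0
        assert np.all(trace.current_pa == 0.0)

    def test_latent_open_fraction_converges_to_stationary_po(self):
        # 60 s sweep: latent open fraction within 2 SE of open/(open+close)
        spec = nc.MarkovChannelSpec(
            open_rate=25.0, close_rate=75.0, sweep_duration_s=60.0, noise_sd_pa=0.0, seed=6
        )
        trace = nc.simulate_single_channel_trace(spec)
        po = spec.stationary_po
        assert po == 0.25
        # SE of the time-averaged occupancy of a two-state process:
        # var ≈ 2 po (1-po) tau_corr / T with tau_corr = 1/(open+close)
        se = np.sqrt(2 * po * (1 - po) / ((spec.open_rate + spec.close_rate) * spec.sweep_duration_s))
        assert abs(trace.latent_open_fraction - po) < 2 * se

    def test_default_sweep_geometry(self):
        spec = nc.MarkovChannelSpec()
        assert spec.sweep_duration_s == 2.0
        trace = nc.simulate_single_channel_trace(spec)
        assert len(trace.current_pa) == 20000


class TestIVCurve:
    def test_noiseless_matches_closed_form(self):
        spec = nc.IVCurveSpec(noise_sd_pa_pf=0.0)
        df = nc.simulate_iv_curve(spec)
        expect = spec.imax_pa_pf * np.exp(-0.5 * ((df["v_mv"] - spec.vmax_mv) / spec.b_mv) ** 2)
        assert np.allclose(df["i_pa_pf"], expect, rtol=0, atol=1e-12)

    def test_peak_identity_at_vmax(self):
        spec = nc.IVCurveSpec(vmax_mv=0.0, voltages_mv=(-20, -10, 0, 10, 20), noise_sd_pa_pf=0.0)
        df = nc.simulate_iv_curve(spec)
        assert df.loc[df["v_mv"] == 0.0, "i_pa_pf"].iloc[0] == spec.imax_pa_pf

    def test_default_protocol_is_13_steps(self):
        df = nc.simulate_iv_curve(nc.IVCurveSpec())
        assert len(df) == 13
        assert df["v_mv"].iloc[0] == -60 and df["v_mv"].iloc[-1] == 60
        assert np.all(np.diff(df["v_mv"]) == 10)


class TestFretTrace:
    def test_zero_amplitude_is_constant(self):
        trace = nc.simulate_fret_trace(nc.FretTraceSpec(response_amplitude=0.0, noise_sd=0.0))
        assert np.all(trace.ratio == trace.ratio[0])

    def test_plateau_closed_form(self):
        spec = nc.FretTraceSpec(response_amplitude=0.10, noise_sd=0.0,
                                treatment_duration_s=3600.0, baseline_ratio=2.0)
        trace = nc.simulate_fret_trace(spec)
        assert trace.ratio[-1] == pytest.approx(0.90 * 2.0, rel=1e-6)

    def test_default_sampling_interval_is_30s(self):
        trace = nc.simulate_fret_trace(nc.FretTraceSpec())
        assert np.allclose(np.diff(trace.time_s), 30.0)
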