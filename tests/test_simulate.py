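import numpy as np
import pytest

from sliderasl import NoiseModel, build_geometry, make_phantom, \
    perfusion_frames, simulate_acquisition, simulate_reference
from sliderasl.geometry import AcquisitionGeometry
from sliderasl.simulate import TISSUE_GM, TISSUE_WM


def thin_single_pass():
    """One-set thin-slice protocol: projection is the identity, so the
    acquired difference frames expose the raw noise model."""
    return AcquisitionGeometry(n_set=1, thin_thickness_mm=2.0,
                               thick_thickness_mm=2.0, mb_factor=2, n_groups=2)


def small_phantom(nz=4):
    return make_phantom(shape=(16, 16, max(nz, 8)), seed=2)


class TestPhantom:
    def test_deterministic_given_seed(self):
        a = make_phantom(shape=(20, 20, 48), seed=5)
        b = make_phantom(shape=(20, 20, 48), seed=5)
        c = make_phantom(shape=(20, 20, 48), seed=6)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert np.any(a.labels != c.labels)

    def test_gm_and_wm_present_in_every_axial_quadrant(self, phantom):
        nx, ny = phantom.labels.shape[:2]
        for xs in (slice(0, nx // 2), slice(nx // 2, nx)):
            for ys in (slice(0, ny // 2), slice(ny // 2, ny)):
                quad = phantom.labels[xs, ys]
                assert np.any(quad == TISSUE_GM)
                assert np.any(quad == TISSUE_WM)

    def test_perfusion_modes_at_tissue_values(self, phantom):
        values, counts = np.unique(phantom.perfusion_map, return_counts=True)
        assert set(values) == {0.0, 20.0, 60.0}
        assert counts.min() > 100

    def test_boundaries_span_many_slices(self, phantom):
        """The GM/WM boundary must cut across slices, not sit on one plane."""
        gm_extent = np.ptp(np.nonzero(phantom.labels == TISSUE_GM)[2])
        assert gm_extent > 20

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_phantom(shape=(4, 4, 96))


class TestAcquisition:
    def test_deterministic_given_seed(self, phantom, slider2):
        noise = NoiseModel(var_thermal=50.0, var_physio=10.0, rho=0.4)
        a = simulate_acquisition(phantom, slider2, noise, n_meas=3, seed=7)
        b = simulate_acquisition(phantom, slider2, noise, n_meas=3, seed=7)
        c = simulate_acquisition(phantom, slider2, noise, n_meas=3, seed=8)
        for sa, sb in zip(a.lr_sets, b.lr_sets):
            np.testing.assert_array_equal(sa.data, sb.data)
        assert np.any(a.lr_sets[0].data != c.lr_sets[0].data)

    def test_noise_free_difference_is_projected_truth(self, phantom, slider2,
                                                      quiet_noise):
        sim = simulate_acquisition(phantom, slider2, quiet_noise, n_meas=4,
                                   seed=0)
        for k, series in enumerate(sim.lr_sets):
            diff = perfusion_frames(series).mean_volume()
            expected = sim.operator.project(sim.truth_perfusion, set_index=k)
            np.testing.assert_allclose(diff, expected, atol=1e-10)

    def test_frame_variance_matches_noise_budget(self):
        """Per-voxel variance of thin-slice difference frames approximates
        g^2 var_thermal + var_physio (single-measurement noise model)."""
        noise = NoiseModel(var_thermal=9.0, var_physio=4.0, rho=0.0)
        sim = simulate_acquisition(small_phantom(), thin_single_pass(), noise,
                                   n_meas=3000, seed=12)
        diff = perfusion_frames(sim.lr_sets[0]).data
        var = diff.var(axis=3, ddof=1).mean()
        assert var == pytest.approx(13.0, rel=0.05)

    def test_g_doubling_quadruples_thermal_variance(self):
        base = NoiseModel(var_thermal=9.0, var_physio=0.0, rho=0.0, g_map=1.0)
        amp = NoiseModel(var_thermal=9.0, var_physio=0.0, rho=0.0, g_map=2.0)
        ph = small_phantom()
        v = []
        for noise in (base, amp):
            sim = simulate_acquisition(ph, thin_single_pass(), noise,
                                       n_meas=2000, seed=3)
            diff = perfusion_frames(sim.lr_sets[0]).data
            v.append(diff.var(axis=3, ddof=1).mean())
        assert v[1] / v[0] == pytest.approx(4.0, rel=0.06)

    def test_thick_slice_thermal_scaling(self, phantom, slider2):
        """Thick-slice acquisitions carry thermal sd reduced by thin/thick
        (the physical thick-slice SNR advantage in mean-signal units)."""
        noise = NoiseModel(var_thermal=16.0, var_physio=0.0, rho=0.0)
        sim = simulate_acquisition(phantom, slider2, noise, n_meas=1500,
                                   seed=4)
        diff = perfusion_frames(sim.lr_sets[0]).data
        var = diff.var(axis=3, ddof=1).mean()
        assert var == pytest.approx(16.0 / 4.0, rel=0.05)

    @pytest.mark.parametrize("rho", [0.0, 0.6])
    def test_physio_lag1_autocorrelation(self, rho):
        noise = NoiseModel(var_thermal=0.0, var_physio=4.0, rho=rho)
        sim = simulate_acquisition(small_phantom(), thin_single_pass(), noise,
                                   n_meas=4000, seed=5)
        diff = perfusion_frames(sim.lr_sets[0]).data
        x = diff - diff.mean(axis=3, keepdims=True)
        lag1 = (x[..., :-1] * x[..., 1:]).mean() / x.var()
        assert lag1 == pytest.approx(rho, abs=0.04)

    def test_invalid_inputs(self, phantom, slider2, quiet_noise):
        with pytest.raises(ValueError, match="n_meas"):
            simulate_acquisition(phantom, slider2, quiet_noise, n_meas=0)
        with pytest.raises(ValueError, match="rho"):
            NoiseModel(var_thermal=1.0, var_physio=1.0, rho=1.0)
        with pytest.raises(ValueError, match="g-factor"):
            NoiseModel(g_map=0.5)
        with pytest.raises(ValueError, match="simulate_reference"):
            simulate_acquisition(phantom, build_geometry("reference"),
                                 quiet_noise, n_meas=1)


class TestReference:
    def test_passes_disjoint_and_union_full(self, phantom, quiet_noise):
        ref = simulate_reference(phantom, build_geometry("reference"),
                                 quiet_noise, n_meas=2, seed=0)
        assert ref.passes[0].n_slices == 24
        assert ref.passes[1].n_slices == 24
        merged = perfusion_frames(ref.merged()).mean_volume()
        np.testing.assert_allclose(merged, ref.truth_perfusion, atol=1e-10)

    def test_reference_noise_matches_thin_model(self, phantom):
        noise = NoiseModel(var_thermal=25.0, var_physio=0.0, rho=0.0)
        ref = simulate_reference(phantom, build_geometry("reference"), noise,
                                 n_meas=1200, seed=6)
        diff = perfusion_frames(ref.passes[0]).data
        assert diff.var(axis=3, ddof=1).mean() == pytest.approx(25.0, rel=0.05)

    def test_requires_reference_geometry(self, phantom, slider2, quiet_noise):
        with pytest.raises(ValueError, match="two-pass"):
            simulate_reference(phantom, slider2, quiet_noise, n_meas=1)
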