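"""Forward model: truth profiles, volume averaging, array sampling, calibration."""

import math

import numpy as np
import pytest
from scipy.special import ndtri

from profile_restore.interp import makima_resample
from profile_restore.metrics import penumbra, pwd
from profile_restore.simulate import (
    BASELINE_PWD_TARGETS_MM,
    DEFAULT_EDGE_SIGMA_MM,
    BeamGeometry,
    DetectorArraySpec,
    Profile,
    SimulationConfig,
    TruthModelParams,
    calibrate_defaults,
    default_truth_params,
    fine_grid,
    generate_dataset,
    makima_baseline,
    sample_array,
    truth_profile,
    volume_average,
)

from conftest import single_erf_params

# 20-80% width of a pure Gaussian-blurred step is 2*Phi^-1(0.8)*sigma
WIDTH_PER_SIGMA = 2.0 * ndtri(0.8)


class TestTruthProfile:
    def test_normalized_to_one_on_axis(self, default_truth):
        assert default_truth.value_at(0.0) == pytest.approx(1.0, abs=1e-12)

    def test_erf_edge_midpoint_is_half(self):
        geo = BeamGeometry(10, 10.0, "in")
        prof = truth_profile(geo, single_erf_params(2.0))
        assert prof.value_at(geo.half_width_mm) == pytest.approx(0.5, abs=1e-6)

    def test_horn_free_erf_width_closed_form(self, erf_profile):
        # sigma = 2 mm -> 1.6832 * sigma = 3.366 mm
        rep = penumbra(erf_profile)
        assert rep.mean_width_mm == pytest.approx(WIDTH_PER_SIGMA * 2.0, abs=0.01)

    def test_geometry_divergence(self):
        geo = BeamGeometry(10, 10.0, "in", ssd_cm=90.0)
        assert geo.half_width_mm == pytest.approx(50.0)
        geo = BeamGeometry(10, 1.5, "in", ssd_cm=90.0)
        assert geo.half_width_mm == pytest.approx(45.75)

    def test_unknown_plane_depth_key_is_configuration_error(self):
        params = single_erf_params(2.0, plane="in", depth=10.0)
        with pytest.raises(KeyError, match="no edge sigma"):
            truth_profile(BeamGeometry(10, 5.0, "in"), params)

    def test_grid_must_cover_measurement_span(self):
        with pytest.raises(ValueError, match="grid must cover"):
            truth_profile(BeamGeometry(10, 10.0, "in"), grid=np.linspace(-100, 100, 2001))

    def test_in_plane_sharper_than_cross_plane_enforced(self):
        with pytest.raises(ValueError, match="in-plane edge sigma"):
            TruthModelParams(edge_sigma_mm={("in", 5.0): 2.5, ("cross", 5.0): 2.0})


class TestVolumeAverage:
    def test_flat_region_invariant(self):
        prof = Profile(np.linspace(-10, 10, 201), np.ones(201))
        out = volume_average(prof, 2.9)
        assert np.max(np.abs(out.values - 1.0)) < 1e-12

    def test_zero_aperture_is_identity(self, erf_profile):
        assert volume_average(erf_profile, 0.0) is erf_profile

    def test_width_growth_matches_quadrature_rule(self):
        # erf sigma=1.5 blurred by a=2.9 rect: width ~ 1.6832*sqrt(s^2 + a^2/12)
        geo = BeamGeometry(10, 10.0, "in")
        prof = truth_profile(geo, single_erf_params(1.5))
        out = volume_average(prof, 2.9)
        expected = WIDTH_PER_SIGMA * math.sqrt(1.5**2 + 2.9**2 / 12.0)
        assert penumbra(out).mean_width_mm == pytest.approx(expected, rel=0.02)

    def test_matches_bruteforce_quadrature(self, erf_profile):
        out = volume_average(erf_profile, 2.9)
        # independent oracle: trapezoid integral over [x-a/2, x+a/2] on a
        # 10x finer linearly interpolated grid
        xs = erf_profile.positions_mm
        fine = np.linspace(xs[0], xs[-1], (xs.size - 1) * 10 + 1)
        vals = np.interp(fine, xs, erf_profile.values)
        for x in (-52.0, -50.0, -48.5, 0.0, 49.0, 51.3):
            sel = (fine >= x - 1.45 - 1e-12) & (fine <= x + 1.45 + 1e-12)
            expected = np.trapezoid(vals[sel], fine[sel]) / 2.9
            assert out.value_at(x) == pytest.approx(expected, abs=5e-5)

    def test_never_increases_maximum_never_narrows_penumbra(self):
        for plane, depth in DEFAULT_EDGE_SIGMA_MM:
            geo = BeamGeometry(5, depth, plane)
            truth = truth_profile(geo)
            blurred = volume_average(truth, 2.9)
            assert blurred.values.max() <= truth.values.max() + 1e-9
            assert penumbra(blurred).mean_width_mm >= penumbra(truth).mean_width_mm - 1e-9

    def test_too_coarse_grid_rejected(self):
        prof = Profile(np.linspace(-10, 10, 21), np.ones(21))  # 1 mm step
        with pytest.raises(ValueError, match="too coarse"):
            volume_average(prof, 2.9)

    def test_aperture_wider_than_support_rejected(self):
        prof = Profile(np.linspace(-1, 1, 41), np.ones(41))
        with pytest.raises(ValueError, match="wider than profile support"):
            volume_average(prof, 3.0)


class TestSampleArray:
    def test_y_axis_reads_averaged_profile(self, default_truth):
        blurred = volume_average(default_truth, 2.9)
        meas = sample_array(blurred, DetectorArraySpec.y_axis())
        assert meas.positions_mm.size == 65
        np.testing.assert_allclose(meas.positions_mm, np.arange(-160, 161, 5.0))
        for p, r in zip(meas.positions_mm, meas.readings):
            assert r == pytest.approx(blurred.value_at(p), abs=1e-9)

    def test_x_axis_has_63_detectors_missing_pm5(self, default_truth):
        meas = sample_array(volume_average(default_truth, 2.9), DetectorArraySpec.x_axis())
        assert meas.positions_mm.size == 63
        assert not np.any(np.isclose(np.abs(meas.positions_mm), 5.0))

    def test_seeded_noise_is_reproducible(self, default_truth):
        blurred = volume_average(default_truth, 2.9)
        spec = DetectorArraySpec.y_axis()
        a = sample_array(blurred, spec, noise_sd=0.01, seed=7)
        b = sample_array(blurred, spec, noise_sd=0.01, seed=7)
        c = sample_array(blurred, spec, noise_sd=0.01, seed=8)
        np.testing.assert_array_equal(a.readings, b.readings)
        assert np.any(a.readings != c.readings)

    def test_offset_and_support_validation(self, default_truth):
        blurred = volume_average(default_truth, 2.9)
        with pytest.raises(ValueError, match="offset"):
            sample_array(blurred, DetectorArraySpec.y_axis(), setup_offset_mm=3.0)
        narrow = Profile(np.linspace(-100, 100, 2001), np.ones(2001))
        with pytest.raises(ValueError, match="outside the profile support"):
            sample_array(narrow, DetectorArraySpec.y_axis())


class TestGenerateDataset:
    def test_default_counts(self):
        records = generate_dataset(SimulationConfig(seed=0))
        assert len(records) == 42
        for rec in records:
            assert rec.truth.value_at(0.0) == pytest.approx(1.0, abs=1e-12)
            n = rec.measurement.positions_mm.size
            assert n == (65 if rec.geometry.plane == "in" else 63)

    def test_replicates_emulate_repeated_sessions(self):
        cfg = SimulationConfig(replicates=3, noise_sd=0.005, seed=1)
        records = generate_dataset(cfg)
        assert len(records) == 126
        seeds = {r.seed for r in records}
        assert len(seeds) == 126  # distinct derived seeds

    def test_restricted_field_set(self):
        cfg = SimulationConfig(field_sizes_cm=(2.0, 4.0, 6.0, 10.0), seed=0)
        assert len(generate_dataset(cfg)) == 24

    def test_deterministic_given_seed(self):
        a = generate_dataset(SimulationConfig(seed=5, noise_sd=0.01))
        b = generate_dataset(SimulationConfig(seed=5, noise_sd=0.01))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.measurement.readings, rb.measurement.readings)


class TestCalibration:
    def test_fine_pitch_zero_aperture_chain_has_negligible_pwd(self):
        # with no aperture and 0.5 mm sampling the forward chain is faithful
        geo = BeamGeometry(10, 10.0, "in")
        truth = truth_profile(geo)
        spec = DetectorArraySpec(np.arange(-160.0, 160.5, 0.5), 0.5, 0.0, "Y")
        meas = sample_array(truth, spec)
        base = makima_resample(meas, 0.5)
        assert abs(pwd(penumbra(base), penumbra(truth))) < 0.05

    def test_shipped_defaults_reproduce_baseline_targets(self):
        params = default_truth_params()
        for (plane, depth), target in BASELINE_PWD_TARGETS_MM.items():
            vals = [
                pwd(penumbra(base), penumbra(truth))
                for truth, base in (
                    makima_baseline(BeamGeometry(f, depth, plane), params)
                    for f in (2, 3, 4, 5, 6, 8, 10)
                )
            ]
            assert np.mean(vals) == pytest.approx(target, abs=0.05)

    def test_calibrated_sigmas_ordered_in_before_cross(self):
        sig = DEFAULT_EDGE_SIGMA_MM
        for depth in (1.5, 5.0, 10.0):
            assert sig[("in", depth)] < sig[("cross", depth)]

    def test_unreachable_target_reports_search_range(self):
        with pytest.raises(RuntimeError, match="no sigma"):
            calibrate_defaults(
                targets={("in", 10.0): 0.0}, sigma_bounds=(0.5, 6.0), tol_mm=0.05
            )

    def test_single_key_recalibration_matches_shipped_value(self):
        params = calibrate_defaults(targets={("in", 10.0): 2.4})
        assert params.edge_sigma_mm[("in", 10.0)] == pytest.approx(
            DEFAULT_EDGE_SIGMA_MM[("in", 10.0)], abs=5e-3
        )
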