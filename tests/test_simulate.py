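"""Generator behaviour: determinism, protocol conformance, known shapes."""

import numpy as np
import pytest

import discmech as dm
from discmech.simulate import trilinear_response


class TestAxialGenerator:
    def test_same_seed_is_bit_identical(self, protocol):
        truth = dm.CurveTruth(noise_sd=2.0)
        a = dm.generate_axial_cycles(protocol, truth, seed=7)
        b = dm.generate_axial_cycles(protocol, truth, seed=7)
        assert np.array_equal(a.response, b.response)
        assert np.array_equal(a.primary, b.primary)

    def test_different_seed_changes_noise(self, protocol):
        truth = dm.CurveTruth(noise_sd=2.0)
        a = dm.generate_axial_cycles(protocol, truth, seed=7)
        b = dm.generate_axial_cycles(protocol, truth, seed=8)
        assert not np.array_equal(a.response, b.response)

    def test_force_extremes_match_protocol_stress_limits(self, protocol, axial_series):
        area = dm.DEFAULT_AREA_MM2
        f_max = protocol.tension_limit * area
        f_min = protocol.compression_limit * area
        assert axial_series.response.max() == pytest.approx(f_max, rel=0.01)
        assert axial_series.response.min() == pytest.approx(f_min, rel=0.01)

    def test_degenerate_single_slope_truth_yields_straight_line(self, protocol):
        k = 150.0
        truth = dm.CurveTruth(nz_stiffness=k, compressive_stiffness=k,
                              tensile_stiffness=k, hysteresis_offset=0.0,
                              noise_sd=0.0)
        series = dm.generate_axial_cycles(protocol, truth, seed=0)
        seg = dm.extract_last_cycle(series, protocol.n_cycles, protocol.frequency)
        x, y = seg.loading_limb("compressive")
        coef = np.polyfit(x, y, 1)
        resid = y - np.polyval(coef, x)
        assert np.max(np.abs(resid)) < 1e-9 * np.ptp(series.response)
        assert coef[0] == pytest.approx(k, rel=1e-9)

    def test_rejects_invalid_sampling_and_sharpness(self, axial_truth):
        with pytest.raises(ValueError):
            dm.LoadingProtocol(samples_per_cycle=20)
        with pytest.raises(ValueError):
            dm.CurveTruth(transition_sharpness=-1.0)

    def test_zero_noise_recovery_of_all_stiffnesses(self, protocol, axial_truth,
                                                    axial_segment):
        """Feeding generator output back through the analysis recovers the
        analytically known truth."""
        p = dm.axial_parameters(axial_segment)
        assert p.compressive_stiffness == pytest.approx(
            axial_truth.compressive_stiffness, rel=0.02)
        assert p.tensile_stiffness == pytest.approx(
            axial_truth.tensile_stiffness, rel=0.02)
        assert p.nz_stiffness == pytest.approx(axial_truth.nz_stiffness, rel=0.02)


class TestTorsionGenerator:
    def test_rotation_sweeps_twice_the_amplitude(self, protocol, torsion_series):
        assert np.ptp(torsion_series.primary) == pytest.approx(
            2 * protocol.rotation_amplitude, rel=1e-12)

    def test_symmetric_truth_gives_equal_cw_ccw_stiffness(self, protocol):
        truth = dm.CurveTruth(nz_half_width=1.0, nz_stiffness=40.0,
                              compressive_stiffness=300.0,
                              tensile_stiffness=300.0, hysteresis_offset=0.0,
                              transition_sharpness=25.0)
        series = dm.generate_torsion_cycles(protocol, truth, seed=0)
        seg = dm.extract_last_cycle(series, protocol.n_cycles, protocol.frequency)
        p = dm.torsional_parameters(seg)
        assert p.cw_stiffness == pytest.approx(p.ccw_stiffness, rel=1e-6)

    def test_asymmetric_limb_average(self, protocol):
        """cw 200, ccw 300 N·mm/deg -> torsional stiffness 250 within 2%."""
        truth = dm.CurveTruth(nz_half_width=1.0, nz_stiffness=30.0,
                              compressive_stiffness=200.0,
                              tensile_stiffness=300.0, hysteresis_offset=0.0,
                              transition_sharpness=25.0)
        series = dm.generate_torsion_cycles(protocol, truth, seed=0)
        seg = dm.extract_last_cycle(series, protocol.n_cycles, protocol.frequency)
        p = dm.torsional_parameters(seg)
        assert p.torsional_stiffness == pytest.approx(250.0, rel=0.02)


class TestFailureGenerator:
    def test_round_trip_strength_and_mode(self):
        truth = dm.FailureTruth(mode="herniation", peak_stress=2.0)
        ramp = dm.generate_failure_ramp(truth, dm.DEFAULT_AREA_MM2, seed=0)
        res = dm.detect_failure(ramp, dm.DEFAULT_AREA_MM2)
        assert res.failure_strength == pytest.approx(2.0, rel=0.01)
        assert res.failure_mode == "herniation"

    def test_endplate_truth_peak_is_global_maximum(self):
        truth = dm.FailureTruth(mode="endplate", rebound=False, peak_stress=3.0)
        ramp = dm.generate_failure_ramp(truth, dm.DEFAULT_AREA_MM2, seed=0)
        stress = ramp.response / dm.DEFAULT_AREA_MM2
        assert stress.max() == pytest.approx(3.0, rel=1e-6)

    def test_full_drop_reaches_zero_force(self):
        truth = dm.FailureTruth(mode="endplate", rebound=False,
                                post_peak_drop_fraction=1.0)
        ramp = dm.generate_failure_ramp(truth, dm.DEFAULT_AREA_MM2, seed=0)
        assert ramp.response.min() == pytest.approx(0.0, abs=1e-9)

    def test_displacement_is_monotone(self):
        ramp = dm.generate_failure_ramp(dm.FailureTruth(), seed=5)
        assert np.all(np.diff(ramp.primary) >= 0)


class TestEndplateGenerator:
    def test_flat_case_exact_height(self):
        profile = dm.generate_endplate_profiles(8.0, 0.0, scale=0.1, seed=0)
        assert dm.average_disc_height(profile) == pytest.approx(8.0, rel=1e-9)

    def test_curved_profiles_match_dense_integration(self):
        profile = dm.generate_endplate_profiles(8.0, 1.0, scale=0.1,
                                                n_points=50, seed=3)
        assert dm.average_disc_height(profile) == pytest.approx(8.0, rel=0.005)

    def test_scale_invariance(self):
        a = dm.generate_endplate_profiles(8.0, 1.0, scale=0.1, seed=2)
        b = dm.EndplateProfile(a.superior * 2.0, a.inferior * 2.0, scale=0.05)
        assert dm.average_disc_height(a) == pytest.approx(
            dm.average_disc_height(b), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dm.generate_endplate_profiles(-1.0, 0.5, scale=0.1)
        with pytest.raises(ValueError):
            dm.generate_endplate_profiles(8.0, -0.5, scale=0.1)


class TestCohortGenerator:
    BASE = {"compressive_stiffness": 220.0, "tensile_stiffness": 120.0}

    def test_large_sample_mean_converges(self):
        spec = dm.CohortSpec(group="defect", n=10_000, pct_change_mean=6.96,
                             pct_change_sd=5.93, seed=11)
        cohort = dm.generate_cohort(spec, self.BASE)
        pct = np.array([c["pct_change"]["compressive_stiffness"] for c in cohort])
        assert pct.mean() == pytest.approx(6.96, abs=0.2)

    def test_zero_sd_gives_identical_percent_change(self):
        spec = dm.CohortSpec(n=5, pct_change_mean=-12.5, pct_change_sd=0.0, seed=0)
        cohort = dm.generate_cohort(spec, self.BASE)
        for c in cohort:
            for key in self.BASE:
                assert c["pct_change"][key] == pytest.approx(-12.5)

    def test_null_spec_gives_unit_ratio(self):
        spec = dm.CohortSpec(n=4, pct_change_mean=0.0, pct_change_sd=0.0, seed=0)
        cohort = dm.generate_cohort(spec, self.BASE)
        for c in cohort:
            for key in self.BASE:
                assert c["treated"][key] / c["intact"][key] == pytest.approx(1.0)
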