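"""Cycle segmentation, limb stiffness and the neutral-zone algorithm."""

import numpy as np
import pytest
from scipy.stats import linregress

import discmech as dm
from discmech.cycles import find_neutral_zone, n_complete_cycles

from conftest import make_segment


class TestExtractLastCycle:
    def test_last_cycle_spans_final_period(self, protocol, axial_series,
                                           axial_segment):
        t = axial_series.time
        period = 1.0 / protocol.frequency
        span = t[axial_segment.end] - t[axial_segment.start]
        dt = t[1] - t[0]
        assert abs(span - period) <= dt + 1e-12
        assert t[axial_segment.end] == pytest.approx(t[-1], abs=dt + 1e-12)

    def test_single_cycle_record_is_whole_record(self, axial_truth):
        prot = dm.LoadingProtocol(n_cycles=1)
        series = dm.generate_axial_cycles(prot, axial_truth, seed=0)
        seg = dm.extract_last_cycle(series, 1, prot.frequency)
        assert seg.start == 0
        assert seg.end == len(series) - 1

    def test_truncated_final_cycle_falls_back_to_previous(self, protocol,
                                                          axial_truth,
                                                          axial_series,
                                                          axial_segment):
        cut = axial_segment.start + (axial_segment.end - axial_segment.start) * 3 // 4
        truncated = dm.MechanicalTimeSeries(axial_series.time[:cut],
                                            axial_series.primary[:cut],
                                            axial_series.response[:cut])
        seg = dm.extract_last_cycle(truncated, protocol.n_cycles, protocol.frequency)
        n = protocol.samples_per_cycle
        assert seg.end == axial_segment.start
        assert seg.start == axial_segment.start - n

    def test_cycle_count_matches_protocol(self, protocol, axial_series):
        assert n_complete_cycles(axial_series, protocol.frequency) == protocol.n_cycles

    def test_less_than_one_cycle_raises(self):
        t = np.linspace(0, 1, 50)
        series = dm.MechanicalTimeSeries(t, t, 2 * t)  # monotone ramp
        with pytest.raises(ValueError, match="cycle"):
            dm.extract_last_cycle(series)


class TestLimbStiffness:
    def test_straight_line(self):
        x = np.linspace(0, 1, 50)
        seg = make_segment(x, 100.0 * x)
        assert dm.limb_stiffness(seg, "tensile") == pytest.approx(100.0)
        assert dm.limb_stiffness(seg, "compressive") == pytest.approx(100.0)

    def test_bilinear_limb_uses_top_fraction_only(self):
        # slope 50 below 0.5 mm, slope 200 above; top 20% lie above 0.5 mm
        x = np.linspace(0, 1, 100)
        y = np.where(x <= 0.5, 50 * x, 25 + 200 * (x - 0.5))
        seg = make_segment(x, y)
        assert dm.limb_stiffness(seg, "tensile") == pytest.approx(200.0, abs=1e-9)

    def test_constant_response_gives_zero(self):
        x = np.linspace(0, 1, 40)
        seg = make_segment(x, np.full_like(x, 5.0))
        assert dm.limb_stiffness(seg, "tensile") == 0.0

    def test_fraction_validation(self):
        x = np.linspace(0, 1, 40)
        seg = make_segment(x, x)
        with pytest.raises(ValueError):
            dm.limb_stiffness(seg, "tensile", fraction=0.0)
        with pytest.raises(ValueError):
            dm.limb_stiffness(seg, "sideways")


class TestRangeOfMotion:
    def test_span(self):
        x = np.linspace(-1.0, 1.5, 60)
        seg = make_segment(x, 10 * x)
        assert dm.range_of_motion(seg) == pytest.approx(2.5)

    def test_torsion_span(self, torsion_segment, protocol):
        assert dm.range_of_motion(torsion_segment) == pytest.approx(
            2 * protocol.rotation_amplitude, rel=1e-9)

    def test_zero_amplitude_warns(self):
        t = np.arange(40.0)
        series = dm.MechanicalTimeSeries(t, np.zeros(40), np.zeros(40))
        seg = dm.CycleSegment(series, 0, 20, 39)
        with pytest.warns(UserWarning):
            assert dm.range_of_motion(seg) == 0.0


def brute_force_seed(x, y, window=15):
    """Independent oracle: argmin |slope| over every contiguous window via
    scipy.stats.linregress, ties broken as the implementation documents."""
    slopes = np.array([linregress(x[i:i + window], y[i:i + window]).slope
                       for i in range(x.size - window + 1)])
    a = np.abs(slopes)
    ties = np.flatnonzero(np.isclose(a, a.min(), rtol=1e-9, atol=0.0))
    if ties.size > 1:
        zc = int(np.argmin(np.abs(y)))
        d = np.abs(ties + (window - 1) / 2 - zc)
        ties = ties[d == d.min()]
    return int(ties[0])


class TestFindNeutralZone:
    def test_straight_line_expands_to_full_curve(self):
        x = np.linspace(-1, 1, 80)
        nz = find_neutral_zone(x, 7.0 * x)
        assert (nz.start, nz.end) == (0, 79)
        assert nz.slope == pytest.approx(7.0, rel=1e-9)
        assert nz.length == pytest.approx(2.0, rel=1e-9)

    def test_plateau_of_trilinear_curve(self, protocol):
        """Region confined to the low-slope plateau; slope within 10%."""
        truth = dm.CurveTruth(nz_stiffness=5.0, compressive_stiffness=100.0,
                              tensile_stiffness=100.0, nz_half_width=0.2,
                              hysteresis_offset=0.0)
        series = dm.generate_axial_cycles(protocol, truth, seed=0)
        seg = dm.extract_last_cycle(series, protocol.n_cycles, protocol.frequency)
        x, y = seg.loading_limb("compressive")
        nz = find_neutral_zone(x, y)
        region = x[nz.start:nz.end + 1]
        lim = 0.2 + truth.transition_width
        assert region.min() >= -lim and region.max() <= lim
        assert abs(nz.slope) == pytest.approx(5.0, rel=0.10)

    def test_seed_window_matches_brute_force(self):
        """Incremental rolling-sum seed equals exhaustive enumeration."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(40, 300))
            x = np.sort(rng.uniform(-1, 1, n))
            y = np.where(x < 0, 80 * x, 15 * x) + rng.normal(0, 0.5, n)
            expected = brute_force_seed(x, y)
            # expansion suppressed (negative growth -> zero threshold) so the
            # returned region is exactly the seed window
            frozen = find_neutral_zone(x, y, se_growth=-1.0)
            assert frozen.start == expected

    def test_noisy_line_median_slope(self):
        """Slope 10 line, 1%-of-range noise: median detection within 5%."""
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(100):
            x = np.linspace(-1, 1, 150)
            y = 10.0 * x + rng.normal(0, 0.01 * 20.0, x.size)
            slopes.append(abs(find_neutral_zone(x, y).slope))
        assert np.median(slopes) == pytest.approx(10.0, rel=0.05)

    def test_short_curve_raises(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            find_neutral_zone(x, x)


class TestAxialParameters:
    def test_zero_noise_truth_recovery(self, axial_truth, axial_segment):
        p = dm.axial_parameters(axial_segment)
        assert p.compressive_stiffness == pytest.approx(
            axial_truth.compressive_stiffness, rel=0.02)
        assert p.tensile_stiffness == pytest.approx(
            axial_truth.tensile_stiffness, rel=0.02)
        assert p.nz_stiffness == pytest.approx(axial_truth.nz_stiffness, rel=0.10)
        assert abs(p.nz_length - axial_truth.nz_length) <= axial_truth.transition_width

    def test_pure_line_all_stiffnesses_equal(self, protocol):
        k = 150.0
        truth = dm.CurveTruth(nz_stiffness=k, compressive_stiffness=k,
                              tensile_stiffness=k, hysteresis_offset=0.0)
        series = dm.generate_axial_cycles(protocol, truth, seed=0)
        seg = dm.extract_last_cycle(series, protocol.n_cycles, protocol.frequency)
        p = dm.axial_parameters(seg)
        for v in (p.compressive_stiffness, p.tensile_stiffness, p.nz_stiffness):
            assert v == pytest.approx(k, rel=1e-6)
        assert p.nz_length == pytest.approx(p.range_of_motion, rel=1e-6)

    def test_response_scaling_covariance(self, axial_segment):
        """Doubling all forces doubles stiffnesses, leaves lengths unchanged."""
        base = dm.axial_parameters(axial_segment)
        s = axial_segment.series
        doubled = dm.MechanicalTimeSeries(s.time, s.primary, 2.0 * s.response)
        seg2 = dm.CycleSegment(doubled, axial_segment.start,
                               axial_segment.trough, axial_segment.end)
        p2 = dm.axial_parameters(seg2)
        assert p2.compressive_stiffness == pytest.approx(
            2 * base.compressive_stiffness, rel=1e-9)
        assert p2.tensile_stiffness == pytest.approx(
            2 * base.tensile_stiffness, rel=1e-9)
        assert p2.nz_stiffness == pytest.approx(2 * base.nz_stiffness, rel=1e-9)
        assert p2.range_of_motion == pytest.approx(base.range_of_motion)
        assert p2.nz_length == pytest.approx(base.nz_length)

    def test_primary_scaling_covariance(self, axial_segment):
        """Scaling displacement by c divides stiffnesses by c and scales
        ROM and NZ length by c."""
        c = 2.5
        base = dm.axial_parameters(axial_segment)
        s = axial_segment.series
        scaled = dm.MechanicalTimeSeries(s.time, c * s.primary, s.response)
        seg2 = dm.CycleSegment(scaled, axial_segment.start,
                               axial_segment.trough, axial_segment.end)
        p2 = dm.axial_parameters(seg2)
        assert p2.compressive_stiffness == pytest.approx(
            base.compressive_stiffness / c, rel=1e-9)
        assert p2.range_of_motion == pytest.approx(c * base.range_of_motion, rel=1e-9)
        assert p2.nz_length == pytest.approx(c * base.nz_length, rel=1e-9)

    def test_mirror_symmetry(self, axial_segment):
        """Negating both channels leaves all reported magnitudes unchanged."""
        base = dm.axial_parameters(axial_segment)
        s = axial_segment.series
        mirrored = dm.MechanicalTimeSeries(s.time, -s.primary, -s.response)
        seg = dm.extract_last_cycle(mirrored)
        p = dm.axial_parameters(seg)
        assert p.range_of_motion == pytest.approx(base.range_of_motion, rel=1e-9)
        assert p.compressive_stiffness == pytest.approx(base.tensile_stiffness,
                                                        rel=1e-6)
        assert p.tensile_stiffness == pytest.approx(base.compressive_stiffness,
                                                    rel=1e-6)
        assert p.nz_stiffness == pytest.approx(base.nz_stiffness, rel=0.02)

    def test_nz_length_never_exceeds_rom(self, protocol):
        rng = np.random.default_rng(3)
        for seed in range(5):
            truth = dm.CurveTruth(noise_sd=float(rng.uniform(0, 3)))
            series = dm.generate_axial_cycles(protocol, truth, seed=seed)
            seg = dm.extract_last_cycle(series, protocol.n_cycles, protocol.frequency)
            p = dm.axial_parameters(seg)
            assert p.nz_length <= p.range_of_motion + 1e-12


class TestTorsionalParameters:
    def test_average_is_exact_mean(self, torsion_segment):
        p = dm.torsional_parameters(torsion_segment)
        assert p.torsional_stiffness == 0.5 * (p.cw_stiffness + p.ccw_stiffness)

    def test_linear_torque_range(self):
        # ccw-max -> cw-max -> ccw-max sweep, torque = 5·rotation over ±4°
        x = np.linspace(4, -4, 100)
        prim = np.concatenate([x, x[::-1][1:]])
        resp = 5.0 * prim
        t = np.arange(prim.size, dtype=float)
        series = dm.MechanicalTimeSeries(t, prim, resp, kind="torsion")
        segment = dm.CycleSegment(series, 0, 99, prim.size - 1)
        p = dm.torsional_parameters(segment)
        assert p.torque_range == pytest.approx(40.0)

    def test_zero_noise_truth_recovery(self, torsion_truth, torsion_segment):
        p = dm.torsional_parameters(torsion_segment)
        assert p.cw_stiffness == pytest.approx(
            torsion_truth.compressive_stiffness, rel=0.02)
        assert p.ccw_stiffness == pytest.approx(
            torsion_truth.tensile_stiffness, rel=0.02)
        assert p.nz_stiffness == pytest.approx(torsion_truth.nz_stiffness, rel=0.10)
        assert abs(p.nz_length - torsion_truth.nz_length) <= \
            torsion_truth.transition_width
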