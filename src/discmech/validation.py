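"""Whole-pipeline verification benchmarks on synthetic ground truth.

Each function here re-runs a stage of the package against the simulator's
analytically known parameters and reports recovery statistics.  They are
used by the test suite and by ``scripts/acceptance.py``; none of them
asserts anything — they measure.
"""

from __future__ import annotations

import numpy as np

from . import simulate
from .cycles import (axial_parameters, extract_last_cycle, find_neutral_zone,
                     torsional_parameters)
from .failure import detect_failure
from .geometry import average_disc_height, cross_sectional_area
from .protocol import CohortSpec, CurveTruth, FailureTruth, LoadingProtocol
from .study import GroupDesign, StudyDesign, cohort_table, run_study

__all__ = [
    "random_test_curve",
    "brute_force_seed_window",
    "nz_seed_oracle_agreement",
    "draw_axial_truth",
    "draw_torsion_truth",
    "zero_noise_recovery",
    "noise_robustness",
    "failure_round_trip",
    "geometry_accuracy",
    "cohort_effect_recovery",
    "determinism_check",
]


# ------------------------------------------------------------------ NZ oracle

def random_test_curve(rng: np.random.Generator, max_points: int = 300):
    """A random noisy curve of the kinds the NZ search meets in practice:
    a line, a blended trilinear sweep, or a smooth cubic, plus noise."""
    n = int(rng.integers(40, max_points + 1))
    x = np.sort(rng.uniform(-1.0, 1.0, n))
    kind = rng.integers(0, 3)
    if kind == 0:
        y = rng.uniform(2.0, 30.0) * x
    elif kind == 1:
        truth = CurveTruth(
            nz_center=float(rng.uniform(-0.2, 0.2)),
            nz_half_width=float(rng.uniform(0.1, 0.3)),
            nz_stiffness=float(rng.uniform(2.0, 20.0)),
            compressive_stiffness=float(rng.uniform(50.0, 150.0)),
            tensile_stiffness=float(rng.uniform(50.0, 150.0)),
            transition_sharpness=float(rng.uniform(10.0, 60.0)))
        y = np.asarray(simulate.trilinear_response(x, truth))
    else:
        c = rng.uniform(-30.0, 30.0, 4)
        y = np.polyval(c, x)
    y = y + rng.normal(0.0, 0.01 * max(np.ptp(y), 1.0), n)
    return x, y


def brute_force_seed_window(x: np.ndarray, y: np.ndarray, window: int = 15) -> int:
    """Exhaustive enumeration oracle: per-window ``np.polyfit`` slope,
    argmin of |slope|, ties broken exactly as the incremental search
    documents (window centre nearest the response zero-crossing, then
    lowest start)."""
    slopes = np.array([np.polyfit(x[i:i + window], y[i:i + window], 1)[0]
                       for i in range(x.size - window + 1)])
    a = np.abs(slopes)
    ties = np.flatnonzero(np.isclose(a, a.min(), rtol=1e-9, atol=0.0))
    if ties.size > 1:
        zc = int(np.argmin(np.abs(y)))
        d = np.abs(ties + (window - 1) / 2.0 - zc)
        ties = ties[d == d.min()]
    return int(ties[0])


def nz_seed_oracle_agreement(n_curves: int = 200, max_points: int = 300,
                             seed: int = 0) -> dict:
    """Fraction of random curves on which the incremental minimal-slope
    seed window equals the exhaustive-enumeration oracle."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_curves):
        x, y = random_test_curve(rng, max_points)
        got = find_neutral_zone(x, y, se_growth=-1.0).start  # expansion off
        if got == brute_force_seed_window(x, y):
            matches += 1
    return {"matches": matches, "n": n_curves}


# ----------------------------------------------------------- truth sampling

def draw_axial_truth(rng: np.random.Generator, noise_sd: float = 0.0) -> CurveTruth:
    """A physiologically plausible random axial truth (bovine caudal range)."""
    nz = float(rng.uniform(10.0, 40.0))
    return CurveTruth(
        nz_center=float(rng.uniform(-0.1, 0.1)),
        nz_half_width=float(rng.uniform(0.25, 0.40)),
        nz_stiffness=nz,
        compressive_stiffness=float(rng.uniform(150.0, 300.0)),
        tensile_stiffness=float(rng.uniform(80.0, 200.0)),
        hysteresis_offset=float(rng.uniform(0.0, 20.0)),
        noise_sd=noise_sd)


def draw_torsion_truth(rng: np.random.Generator, noise_sd: float = 0.0) -> CurveTruth:
    nz = float(rng.uniform(20.0, 60.0))
    return CurveTruth(
        nz_center=float(rng.uniform(-0.3, 0.3)),
        nz_half_width=float(rng.uniform(0.8, 1.2)),
        nz_stiffness=nz,
        compressive_stiffness=float(rng.uniform(220.0, 380.0)),
        tensile_stiffness=float(rng.uniform(220.0, 380.0)),
        hysteresis_offset=float(rng.uniform(0.0, 100.0)),
        noise_sd=noise_sd,
        transition_sharpness=25.0)


# ------------------------------------------------------ parameter recovery

def _axial_errors(protocol: LoadingProtocol, truth: CurveTruth, seed: int) -> dict:
    series = simulate.generate_axial_cycles(protocol, truth, seed)
    seg = extract_last_cycle(series, protocol.n_cycles, protocol.frequency)
    p = axial_parameters(seg)
    return {
        "compressive": abs(p.compressive_stiffness - truth.compressive_stiffness)
        / truth.compressive_stiffness,
        "tensile": abs(p.tensile_stiffness - truth.tensile_stiffness)
        / truth.tensile_stiffness,
        "nz_stiffness": abs(p.nz_stiffness - truth.nz_stiffness)
        / truth.nz_stiffness,
        "nz_length_dev": abs(p.nz_length - truth.nz_length),
        "transition_width": truth.transition_width,
    }


def _torsion_errors(protocol: LoadingProtocol, truth: CurveTruth, seed: int) -> dict:
    series = simulate.generate_torsion_cycles(protocol, truth, seed)
    seg = extract_last_cycle(series, protocol.n_cycles, protocol.frequency)
    p = torsional_parameters(seg)
    avg = 0.5 * (truth.compressive_stiffness + truth.tensile_stiffness)
    return {
        "cw": abs(p.cw_stiffness - truth.compressive_stiffness)
        / truth.compressive_stiffness,
        "ccw": abs(p.ccw_stiffness - truth.tensile_stiffness)
        / truth.tensile_stiffness,
        "average": abs(p.torsional_stiffness - avg) / avg,
        "nz_stiffness": abs(p.nz_stiffness - truth.nz_stiffness)
        / truth.nz_stiffness,
        "nz_length_dev": abs(p.nz_length - truth.nz_length),
        "transition_width": truth.transition_width,
    }


def zero_noise_recovery(n_tests: int = 50, seed: int = 0) -> dict:
    """Noise-free round trips with randomized truths; per-test errors."""
    protocol = LoadingProtocol()
    rng = np.random.default_rng(seed)
    axial = [_axial_errors(protocol, draw_axial_truth(rng), seed=i)
             for i in range(n_tests)]
    torsion = [_torsion_errors(protocol, draw_torsion_truth(rng), seed=i)
               for i in range(n_tests)]
    return {"axial": axial, "torsion": torsion}


def noise_robustness(noise_fracs=(0.0, 0.005, 0.01, 0.02, 0.05),
                     n_seeds: int = 50, seed: int = 0,
                     n_seeds_at_1pct: int | None = None) -> dict:
    """Median recovery errors of the default axial truth vs noise level
    (noise expressed as a fraction of the protocol force range)."""
    protocol = LoadingProtocol()
    area = simulate.DEFAULT_AREA_MM2
    force_range = (protocol.tension_limit - protocol.compression_limit) * area
    out = {}
    for frac in noise_fracs:
        n = n_seeds_at_1pct if (frac == 0.01 and n_seeds_at_1pct) else n_seeds
        truth = CurveTruth(noise_sd=frac * force_range)
        errs = [_axial_errors(LoadingProtocol(), truth, seed=seed + i)
                for i in range(n)]
        out[frac] = {
            "compressive_median": float(np.median([e["compressive"] for e in errs])),
            "tensile_median": float(np.median([e["tensile"] for e in errs])),
            "nz_stiffness_median": float(np.median(
                [e["nz_stiffness"] for e in errs])),
            "n": n,
        }
    return out


# ------------------------------------------------------------------ failure

def failure_round_trip(n_per_mode: int = 50, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    area = simulate.DEFAULT_AREA_MM2
    results = {}
    for mode, rebound in (("herniation", True), ("endplate", False)):
        strength_errs, mode_ok = [], 0
        for i in range(n_per_mode):
            truth = FailureTruth(
                mode=mode, rebound=rebound,
                peak_stress=float(rng.uniform(1.0, 4.0)),
                peak_displacement=float(rng.uniform(2.0, 4.0)),
                post_peak_drop_fraction=float(rng.uniform(0.25, 0.6)),
                noise_sd=0.005)
            ramp = simulate.generate_failure_ramp(truth, area,
                                                  seed=seed + 1000 + i)
            res = detect_failure(ramp, area)
            if res.failure_strength is not None:
                strength_errs.append(abs(res.failure_strength - truth.peak_stress)
                                     / truth.peak_stress)
            else:
                strength_errs.append(1.0)
            mode_ok += res.failure_mode == mode
        results[mode] = {"strength_err_max": float(np.max(strength_errs)),
                         "strength_err_median": float(np.median(strength_errs)),
                         "mode_recovery": mode_ok / n_per_mode}
    return results


# ----------------------------------------------------------------- geometry

def geometry_accuracy(seed: int = 0) -> dict:
    flat = simulate.generate_endplate_profiles(8.0, 0.0, scale=0.1, seed=seed)
    curved = simulate.generate_endplate_profiles(8.0, 1.0, scale=0.1,
                                                 n_points=50, seed=seed)
    return {
        "flat_err": abs(average_disc_height(flat) - 8.0) / 8.0,
        "curved_err": abs(average_disc_height(curved) - 8.0) / 8.0,
        "circle_area_rel_err": abs(cross_sectional_area(20.0)
                                   - np.pi * 100.0) / (np.pi * 100.0),
        "ellipse_area_rel_err": abs(cross_sectional_area(20.0, 10.0)
                                    - np.pi * 50.0) / (np.pi * 50.0),
    }


# -------------------------------------------------------------------- study

def cohort_effect_recovery(seed: int = 0, n_specimens: int = 10) -> dict:
    """Injected −30% tensile-stiffness group effect at zero noise, plus the
    large-n percent-change convergence of the cohort generator at the
    defect-scale distribution (+6.96 ± 5.93%)."""
    design = StudyDesign(groups=(
        GroupDesign(name="Defect", n=n_specimens,
                    axial_perturb={"tensile_stiffness": -30.0}),))
    records = run_study(design, seed=seed)
    ratios = [r.ratios["axial_tensile_stiffness"] for r in records
              if r.error is None]
    spec = CohortSpec(group="defect", n=10_000, pct_change_mean=6.96,
                      pct_change_sd=5.93, seed=seed)
    cohort = simulate.generate_cohort(spec, {"compressive_stiffness": 220.0})
    pct = [c["pct_change"]["compressive_stiffness"] for c in cohort]
    null = run_study(StudyDesign(groups=(GroupDesign(name="Intact", n=2),)),
                     seed=seed)
    null_dev = max(abs(v - 1.0) for r in null for v in r.ratios.values())
    return {"tensile_ratio_mean": float(np.mean(ratios)),
            "n_ratio": len(ratios),
            "cohort_pct_mean": float(np.mean(pct)),
            "null_ratio_max_dev": float(null_dev)}


# -------------------------------------------------------------- determinism

def determinism_check(seed: int = 0) -> dict:
    """Every seeded pathway, run twice: outputs must be bit-identical."""
    protocol = LoadingProtocol()
    truth = CurveTruth(noise_sd=2.0)
    checks = {}
    a = simulate.generate_axial_cycles(protocol, truth, seed)
    b = simulate.generate_axial_cycles(protocol, truth, seed)
    checks["axial"] = bool(np.array_equal(a.response, b.response))
    tt = simulate.default_torsion_truth(noise_sd=5.0)
    a = simulate.generate_torsion_cycles(protocol, tt, seed)
    b = simulate.generate_torsion_cycles(protocol, tt, seed)
    checks["torsion"] = bool(np.array_equal(a.response, b.response))
    ft = FailureTruth(noise_sd=0.01)
    a = simulate.generate_failure_ramp(ft, seed=seed)
    b = simulate.generate_failure_ramp(ft, seed=seed)
    checks["failure"] = bool(np.array_equal(a.response, b.response))
    a = simulate.generate_endplate_profiles(8.0, 1.0, 0.1, seed=seed)
    b = simulate.generate_endplate_profiles(8.0, 1.0, 0.1, seed=seed)
    checks["endplate"] = bool(np.array_equal(a.superior, b.superior))
    spec = CohortSpec(n=20, pct_change_mean=5.0, pct_change_sd=2.0, seed=seed)
    base = {"k": 100.0}
    checks["cohort"] = simulate.generate_cohort(spec, base) == \
        simulate.generate_cohort(spec, base)
    design = StudyDesign(groups=(GroupDesign(name="g", n=1),), noise_sd_frac=0.005)
    ta = cohort_table(run_study(design, seed=seed))
    tb = cohort_table(run_study(design, seed=seed))
    checks["study"] = bool(ta.equals(tb))
    return checks
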