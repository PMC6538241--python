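"""Synthetic motion-segment test generator with analytically known truth.

Every generator emulates the cyclic/failure loading protocol applied to
bovine caudal motion segments and the qualitative morphology of the
measured curves: sigmoidal loading limbs with a low-slope neutral zone,
a hysteresis loop between the loading and unloading limbs, and ramp-to-
failure curves with a characteristic peak.  Because the underlying
constitutive law is a logistic-blended trilinear stiffness profile, the
neutral-zone centre, width and stiffness and both flank stiffnesses are
known exactly, which gives every analysis stage a parameter-recovery test
surface without laboratory data.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .geometry import EndplateProfile
from .protocol import CohortSpec, CurveTruth, FailureTruth, LoadingProtocol
from .timeseries import AXIAL, TORSION, MechanicalTimeSeries

__all__ = [
    "DEFAULT_AREA_MM2",
    "trilinear_stiffness",
    "trilinear_response",
    "generate_axial_cycles",
    "generate_torsion_cycles",
    "generate_failure_ramp",
    "generate_endplate_profiles",
    "generate_cohort",
    "default_torsion_truth",
]

#: Cross-sectional area (mm²) of a 20 mm diameter caudal disc, the default
#: specimen geometry for converting protocol stress limits into forces.
DEFAULT_AREA_MM2 = float(np.pi * 10.0**2)


def _softplus(x: np.ndarray | float) -> np.ndarray:
    return np.logaddexp(0.0, x)


def trilinear_stiffness(x, truth: CurveTruth):
    """Local slope of the loading limb at primary position ``x``.

    Logistic blend between ``nz_stiffness`` inside the neutral zone and the
    compressive/tensile flank stiffnesses outside it.
    """
    s = truth.transition_sharpness
    lo = truth.nz_center - truth.nz_half_width
    hi = truth.nz_center + truth.nz_half_width
    x = np.asarray(x, dtype=float)
    sig_lo = 1.0 / (1.0 + np.exp(-s * (lo - x)))   # -> 1 deep in compression
    sig_hi = 1.0 / (1.0 + np.exp(-s * (x - hi)))   # -> 1 deep in tension
    return (truth.nz_stiffness
            + (truth.compressive_stiffness - truth.nz_stiffness) * sig_lo
            + (truth.tensile_stiffness - truth.nz_stiffness) * sig_hi)


def trilinear_response(x, truth: CurveTruth):
    """Exact integral of :func:`trilinear_stiffness`, zero at the NZ centre."""
    s = truth.transition_sharpness
    c = truth.nz_center
    lo = c - truth.nz_half_width
    hi = c + truth.nz_half_width
    x = np.asarray(x, dtype=float)
    dk_c = truth.compressive_stiffness - truth.nz_stiffness
    dk_t = truth.tensile_stiffness - truth.nz_stiffness
    f = (truth.nz_stiffness * (x - c)
         - dk_c / s * _softplus(s * (lo - x))
         + dk_t / s * _softplus(s * (x - hi)))
    f0 = (- dk_c / s * _softplus(s * (lo - c))
          + dk_t / s * _softplus(s * (c - hi)))
    return f - f0


def _invert_response(target: float, truth: CurveTruth) -> float:
    """Primary position at which the loading-limb response equals ``target``."""
    k_min = max(truth.nz_stiffness, 1e-6)
    span = abs(target) / k_min + truth.nz_half_width + 10.0 / truth.transition_sharpness
    lo, hi = truth.nz_center - span, truth.nz_center + span
    return brentq(lambda x: float(trilinear_response(x, truth)) - target, lo, hi,
                  xtol=1e-12)


def _cycle_samples(protocol: LoadingProtocol) -> np.ndarray:
    n = protocol.n_cycles * protocol.samples_per_cycle + 1
    return np.linspace(0.0, protocol.n_cycles * protocol.period, n)


def _cycles(protocol: LoadingProtocol, truth: CurveTruth, seed: int,
            x_max: float, x_min: float, kind: str) -> MechanicalTimeSeries:
    """Shared cyclic kernel: cosine sweep of the primary axis between
    ``x_max`` (tension/ccw) and ``x_min`` (compression/cw)."""
    rng = np.random.default_rng(seed)
    t = _cycle_samples(protocol)
    mid = 0.5 * (x_max + x_min)
    amp = 0.5 * (x_max - x_min)
    phase = 2.0 * np.pi * protocol.frequency * t
    x = mid + amp * np.cos(phase)
    # primary velocity sign: >= 0 on the tension-/ccw-directed (loading) sweep
    toward_tension = -np.sin(phase) >= 0.0
    offset = np.where(toward_tension, 0.5, -0.5) * truth.hysteresis_offset
    y = trilinear_response(x, truth) + offset
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=y.shape)
    return MechanicalTimeSeries(t, x, y, kind=kind,
                                meta={"seed": seed, "truth": truth, "protocol": protocol})


def generate_axial_cycles(protocol: LoadingProtocol, truth: CurveTruth,
                          seed: int, area_mm2: float = DEFAULT_AREA_MM2,
                          ) -> MechanicalTimeSeries:
    """Simulate a cyclic axial tension–compression test.

    The displacement sweep is sized so that the loading limbs reach the
    protocol's effective-stress limits times ``area_mm2``: the force record
    spans ``compression_limit*area`` to ``tension_limit*area`` exactly
    (before noise).  Tension positive, compression negative.
    """
    h = truth.hysteresis_offset
    f_top = protocol.tension_limit * area_mm2 - 0.5 * h     # on loading-to-tension limb
    f_bot = protocol.compression_limit * area_mm2 + 0.5 * h  # on loading-to-compression limb
    if f_top <= f_bot:
        raise ValueError("hysteresis offset exceeds the protocol force span")
    x_max = _invert_response(f_top, truth)
    x_min = _invert_response(f_bot, truth)
    return _cycles(protocol, truth, seed, x_max, x_min, AXIAL)


def default_torsion_truth(noise_sd: float = 0.0) -> CurveTruth:
    """Representative torsional truth for an intact bovine caudal segment
    (stiffness slots read as clockwise=compressive, counterclockwise=tensile,
    in N·mm/deg)."""
    return CurveTruth(nz_center=0.0, nz_half_width=1.0, nz_stiffness=40.0,
                      compressive_stiffness=300.0, tensile_stiffness=320.0,
                      hysteresis_offset=60.0, noise_sd=noise_sd,
                      transition_sharpness=25.0)


def generate_torsion_cycles(protocol: LoadingProtocol, truth: CurveTruth,
                            seed: int) -> MechanicalTimeSeries:
    """Simulate a cyclic torsion test sweeping ±``rotation_amplitude``.

    Rotation is actuator-controlled, so the sweep covers the full ±amplitude
    regardless of the torque that develops.  Counterclockwise positive; the
    truth's compressive/tensile stiffness slots are the clockwise and
    counterclockwise limb stiffnesses.
    """
    return _cycles(protocol, truth, seed,
                   x_max=protocol.rotation_amplitude,
                   x_min=-protocol.rotation_amplitude, kind=TORSION)


def generate_failure_ramp(truth: FailureTruth, area: float = DEFAULT_AREA_MM2,
                          seed: int = 0, rate_mm_per_min: float = 2.0,
                          sample_hz: float = 10.0) -> MechanicalTimeSeries:
    """Simulate a displacement-controlled compression-to-failure ramp.

    Stress rises smoothly to ``peak_stress`` at ``peak_displacement``, drops
    by ``post_peak_drop_fraction`` over a short displacement window, then
    either rebounds (herniation: the extruding nucleus unloads partially and
    stress re-rises as the endplates approach) or declines without recovery
    (endplate fracture).  ``force = stress × area``.
    """
    rng = np.random.default_rng(seed)
    dp = truth.peak_displacement
    d_end = 2.0 * dp
    duration = d_end / (rate_mm_per_min / 60.0)
    n = max(int(duration * sample_hz), 200) + 1
    t = np.linspace(0.0, duration, n)
    d = d_end * t / duration
    peak = truth.peak_stress
    trough = peak * (1.0 - truth.post_peak_drop_fraction)
    w = 0.15 * dp                      # displacement width of the drop
    d1 = dp + w
    stress = np.empty_like(d)
    rise = d <= dp
    stress[rise] = peak * np.sin(0.5 * np.pi * d[rise] / dp) ** 2
    drop = (d > dp) & (d <= d1)
    stress[drop] = trough + (peak - trough) * 0.5 * (
        1.0 + np.cos(np.pi * (d[drop] - dp) / w))
    tail = d > d1
    if truth.mode == "herniation" and truth.rebound:
        # endplates approach through the herniated void: accelerating re-rise
        frac = (d[tail] - d1) / (d_end - d1)
        stress[tail] = trough + 0.8 * peak * frac**2
    else:
        stress[tail] = np.maximum(trough - 0.05 * peak * (d[tail] - d1) / dp, 0.0)
    if truth.noise_sd > 0:
        stress = stress + rng.normal(0.0, truth.noise_sd, size=stress.shape)
    # convention: the ramp is recorded as magnitudes (stress-displacement curve)
    return MechanicalTimeSeries(t, d, stress * area, kind=AXIAL,
                                meta={"seed": seed, "truth": truth, "area_mm2": area})


def generate_endplate_profiles(mean_height: float, curvature_depth: float,
                               scale: float, n_points: int = 50, seed: int = 0,
                               lateral_span_mm: float = 20.0,
                               ) -> EndplateProfile:
    """Digitized superior/inferior endplate polylines of known mean height.

    Both endplates carry a parabolic convexity of depth ``curvature_depth``
    (mm) bulging into the disc; the gap is constructed so that its exact
    lateral average equals ``mean_height``.  Coordinates are returned in
    pixels at ``scale`` mm/pixel, with seeded jitter of the digitization
    x-positions emulating hand-clicked points.
    """
    if mean_height <= 0:
        raise ValueError("mean_height must be positive")
    if curvature_depth < 0:
        raise ValueError("curvature_depth must be >= 0")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if n_points < 2:
        raise ValueError("need at least 2 points per polyline")
    rng = np.random.default_rng(seed)
    L = lateral_span_mm

    def sample_x() -> np.ndarray:
        x = np.linspace(0.0, L, n_points)
        if n_points > 2:
            jitter = rng.uniform(-0.25, 0.25, size=n_points - 2) * (L / (n_points - 1))
            x[1:-1] += jitter
        return x

    def gap(x: np.ndarray) -> np.ndarray:
        bump = 1.0 - (2.0 * x / L - 1.0) ** 2          # mean over [0, L] is 2/3
        return mean_height + 2.0 * curvature_depth * (2.0 / 3.0 - bump)

    y0 = 30.0  # arbitrary image-frame offset, mm
    xs, xi = sample_x(), sample_x()
    sup = np.column_stack([xs, y0 + 0.5 * gap(xs)]) / scale
    inf = np.column_stack([xi, y0 - 0.5 * gap(xi)]) / scale
    return EndplateProfile(superior=sup, inferior=inf, scale=scale)


def _as_mapping(params) -> dict:
    if is_dataclass(params) and not isinstance(params, type):
        return asdict(params)
    if isinstance(params, Mapping):
        return dict(params)
    raise TypeError("baseline must be a dataclass or mapping of parameter values")


def generate_cohort(spec: CohortSpec, baseline) -> list[dict]:
    """Simulate paired intact/treated parameter sets for one group.

    Each specimen's intact values jitter around ``baseline`` with relative
    SD ``intact_cv``; treated values apply a percent change drawn from
    Normal(``pct_change_mean``, ``pct_change_sd``) independently per
    parameter (per-parameter overrides via ``spec.per_parameter``).
    """
    base = _as_mapping(baseline)
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for i in range(spec.n):
        intact, treated, pct = {}, {}, {}
        for key, value in base.items():
            mean_sd = spec.per_parameter.get(key, (spec.pct_change_mean, spec.pct_change_sd))
            iv = value * (1.0 + spec.intact_cv * rng.standard_normal())
            p = rng.normal(mean_sd[0], mean_sd[1])
            intact[key] = iv
            treated[key] = iv * (1.0 + p / 100.0)
            pct[key] = p
        cohort.append({"specimen": f"{spec.group}-{i + 1:03d}", "group": spec.group,
                       "intact": intact, "treated": treated, "pct_change": pct})
    return cohort
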