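"""Biomechanical parameter extraction from cyclic motion-segment tests.

From the final loading cycle of an axial (force-displacement) or torsional
(torque-rotation) record this module extracts:

* range of motion / torque range,
* compressive & tensile (or clockwise & counterclockwise) stiffness —
  ordinary least-squares slope over the top 20% of the loading-portion
  points of each limb (ranked by load in the limb's own direction),
* the neutral zone (NZ) — the minimal-|slope| region of the curve, located
  by a 15-point moving-window linear regression seeded at the window of
  smallest absolute slope and greedily expanded point by point on either
  side while the refitted regression standard error stays within 10% of
  the seed window's; the NZ length is the primary-axis extent of the accepted
  region and the NZ stiffness its fitted slope magnitude.

Sign convention: tension/counterclockwise positive, compression/clockwise
negative; all reported stiffnesses are positive magnitudes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .timeseries import TORSION, MechanicalTimeSeries

__all__ = [
    "CycleSegment",
    "NeutralZoneRegion",
    "AxialParameters",
    "TorsionalParameters",
    "extract_last_cycle",
    "n_complete_cycles",
    "limb_stiffness",
    "range_of_motion",
    "find_neutral_zone",
    "axial_parameters",
    "torsional_parameters",
]


# --------------------------------------------------------------------------
# cycle segmentation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleSegment:
    """The final complete cycle of a cyclic record.

    ``start`` and ``end`` index the opening and closing maximum-tension
    (or max-counterclockwise) peaks of the primary channel; ``trough`` the
    intervening maximum-compression (max-clockwise) extreme.  The two
    loading limbs are start→trough (compressive/clockwise loading, which is
    simultaneously the tensile-side unloading) and trough→end
    (tensile/counterclockwise loading).
    """

    series: MechanicalTimeSeries
    start: int
    trough: int
    end: int

    def __post_init__(self) -> None:
        n = len(self.series)
        if not (0 <= self.start < self.trough < self.end < n):
            raise ValueError("cycle indices must satisfy 0 <= start < trough < end < n")

    @property
    def primary(self) -> np.ndarray:
        return self.series.primary[self.start:self.end + 1]

    @property
    def response(self) -> np.ndarray:
        return self.series.response[self.start:self.end + 1]

    def loading_limb(self, limb: str) -> tuple[np.ndarray, np.ndarray]:
        """Time-ordered (primary, response) points of one loading limb.

        ``"compressive"``/``"cw"``: the sweep toward the negative extreme;
        ``"tensile"``/``"ccw"``: the sweep back toward the positive extreme.
        """
        s = self.series
        if limb in ("compressive", "cw"):
            sl = slice(self.start, self.trough + 1)
        elif limb in ("tensile", "ccw"):
            sl = slice(self.trough, self.end + 1)
        else:
            raise ValueError(f"unknown limb {limb!r}")
        return s.primary[sl], s.response[sl]


def _alternating_extrema(x: np.ndarray, distance: int) -> list[tuple[int, int]]:
    """(index, sign) events; sign +1 for maxima, -1 for minima, alternating."""
    peaks, _ = find_peaks(x, distance=distance)
    troughs, _ = find_peaks(-x, distance=distance)
    events = sorted([(int(i), 1) for i in peaks] + [(int(i), -1) for i in troughs])
    if not events:
        return []
    # record boundaries act as extrema of the opposite sign to their neighbour
    i0, s0 = events[0]
    if s0 == -1 and x[0] > x[i0]:
        events.insert(0, (0, 1))
    elif s0 == 1 and x[0] < x[i0]:
        events.insert(0, (0, -1))
    i1, s1 = events[-1]
    last = x.size - 1
    if s1 == -1 and x[last] > x[i1]:
        events.append((last, 1))
    elif s1 == 1 and x[last] < x[i1]:
        events.append((last, -1))
    # enforce alternation, keeping the more extreme of equal-sign neighbours
    cleaned: list[tuple[int, int]] = []
    for idx, sign in events:
        if cleaned and cleaned[-1][1] == sign:
            prev_idx = cleaned[-1][0]
            if sign * (x[idx] - x[prev_idx]) > 0:
                cleaned[-1] = (idx, sign)
        else:
            cleaned.append((idx, sign))
    return cleaned


def extract_last_cycle(series: MechanicalTimeSeries,
                       n_cycles: int | None = None,
                       frequency: float | None = None,
                       closure_fraction: float = 0.9) -> CycleSegment:
    """Locate the last complete cycle by extrema of the primary channel.

    ``frequency`` (with the record's sampling rate) sets the minimum
    extremum spacing; without it a 5-sample spacing is used, which is ample
    for actuator-controlled primaries.  A trailing partial cycle is
    discarded: the closing peak must recover at least ``closure_fraction``
    of the opening peak's amplitude above the trough.
    """
    x = series.primary
    if frequency is not None:
        dt = float(np.median(np.diff(series.time)))
        distance = max(int(0.5 / (frequency * dt)), 1)
    else:
        distance = 5
    events = _alternating_extrema(x, distance)
    peaks = [i for i, s in events if s == 1]
    n_found = max(len(peaks) - 1, 0)
    if len(events) < 3 or n_found < 1:
        raise ValueError(
            f"record does not contain one complete cycle "
            f"({n_found} complete cycles found)")
    pos = {idx: k for k, (idx, _) in enumerate(events)}
    # walk peak pairs from the end until a properly closed cycle is found
    for j in range(len(peaks) - 1, 0, -1):
        p0, p1 = peaks[j - 1], peaks[j]
        between = events[pos[p0] + 1:pos[p1]]
        trough_candidates = [i for i, s in between if s == -1]
        if not trough_candidates:
            continue
        trough = min(trough_candidates, key=lambda i: x[i])
        amp0 = x[p0] - x[trough]
        if amp0 <= 0:
            continue
        if x[p1] - x[trough] >= closure_fraction * amp0:
            return CycleSegment(series, p0, trough, p1)
    raise ValueError("no complete, properly closed cycle found")


def n_complete_cycles(series: MechanicalTimeSeries,
                      frequency: float | None = None) -> int:
    """Number of complete (peak-to-peak) cycles found in the record."""
    if frequency is not None:
        dt = float(np.median(np.diff(series.time)))
        distance = max(int(0.5 / (frequency * dt)), 1)
    else:
        distance = 5
    events = _alternating_extrema(series.primary, distance)
    peaks = [i for i, s in events if s == 1]
    return max(len(peaks) - 1, 0)


def range_of_motion(segment: CycleSegment) -> float:
    """Total primary-axis excursion of the cycle (max − min), mm or deg."""
    rom = float(np.ptp(segment.primary))
    if rom == 0.0:
        warnings.warn("zero-amplitude cycle: range of motion is 0", stacklevel=2)
    return rom


# --------------------------------------------------------------------------
# limb stiffness
# --------------------------------------------------------------------------

def limb_stiffness(segment: CycleSegment, limb: str, fraction: float = 0.20) -> float:
    """OLS stiffness of one loading limb from its top-load points.

    The slope is fitted over the ``fraction`` of the limb's loading-portion
    points carrying the largest load in the limb's own direction (most
    negative response for the compressive/clockwise limb, most positive for
    the tensile/counterclockwise limb; at least 3 points) and reported as a
    positive magnitude: N/mm for axial limbs, N·mm/deg for torsional ones.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    x, y = segment.loading_limb(limb)
    n_sel = max(math.ceil(fraction * x.size), 3)
    if x.size < n_sel or x.size < 3:
        raise ValueError(
            f"limb holds {x.size} points; need at least {max(n_sel, 3)} for the fit")
    direction = -1.0 if limb in ("compressive", "cw") else 1.0
    keep = np.argsort(direction * y)[-n_sel:]
    slope, _, _ = _ols(x[keep], y[keep])
    return abs(slope)


# --------------------------------------------------------------------------
# neutral zone
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralZoneRegion:
    """Accepted neutral-zone window of one analyzed limb.

    ``start``/``end`` are inclusive indices into the limb curve the search
    ran on; ``slope`` is the signed refitted slope of the accepted region,
    ``slope_se`` its standard error, and ``seed_se`` the standard error of
    the initial minimal-slope window that anchored the expansion.
    """

    start: int
    end: int
    slope: float
    slope_se: float
    seed_se: float
    length: float          # primary-axis extent, mm or deg
    limb: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < 2:
            raise ValueError("neutral-zone region must span at least 2 points")

    @property
    def stiffness(self) -> float:
        return abs(self.slope)


def _ols(x: np.ndarray, y: np.ndarray, se_kind: str = "slope") -> tuple[float, float, float]:
    """Least-squares line fit returning (slope, slope SE or residual SE, sxx)."""
    n = x.size
    xb, yb = x.mean(), y.mean()
    dx = x - xb
    sxx = float(dx @ dx)
    if sxx == 0.0:
        return 0.0, np.inf, 0.0
    slope = float(dx @ (y - yb)) / sxx
    resid = y - yb - slope * dx
    sse = float(resid @ resid)
    dof = n - 2
    if dof <= 0:
        return slope, np.inf, sxx
    if se_kind == "slope":
        se = math.sqrt(max(sse, 0.0) / dof / sxx)
    elif se_kind == "residual":
        se = math.sqrt(max(sse, 0.0) / dof)
    else:
        raise ValueError("se_kind must be 'slope' or 'residual'")
    return slope, se, sxx


def _window_slopes(x: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Slopes of every contiguous ``window``-point OLS fit, via rolling sums."""
    w = window
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    sx = c1[w:] - c1[:-w]
    sxx = c2[w:] - c2[:-w]
    sy = cy[w:] - cy[:-w]
    sxy = cxy[w:] - cxy[:-w]
    den = w * sxx - sx * sx
    num = w * sxy - sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return slopes


def find_neutral_zone(x: np.ndarray, y: np.ndarray, window: int = 15,
                      se_growth: float = 0.10, se_kind: str = "residual",
                      resolution: float | None = None,
                      limb: str = "") -> NeutralZoneRegion:
    """Locate the minimal-slope (neutral-zone) region of a loading limb.

    Algorithm: (i) fit an OLS line to every contiguous ``window``-point
    span and seed at the window of minimal |slope| (ties broken by the
    window whose centre is nearest the response zero-crossing, then by the
    lowest start index); (ii) expand the region one point at a time,
    alternating sides, accepting an expansion only while the refitted
    standard error stays within ``se_growth`` (default 10%) of the seed
    window's; a rejected side is not revisited.

    ``se_kind`` selects the expansion statistic: the regression's residual
    standard error (default) or the slope standard error.  The residual SE
    is the statistic that makes the stopping rule meaningful — it stays
    flat while the window grows inside a straight region and jumps at a
    stiffness transition, whereas the slope SE *falls* as the window's
    x-spread grows, so a bound fixed at the seed window never trips.

    The expansion baseline is the seed window's SE floored at two scales
    below which SE differences carry no information: the curve's ambient
    noise level, estimated robustly from second differences (which cancel
    any locally linear trend), and the load-cell measurement
    ``resolution`` in response units (default: 0.1% of the curve's
    response range).  Without the noise floor, a seed window whose local
    noise happens to fit unusually well would stop the expansion
    immediately; without the resolution floor, a noise-free record — whose
    windowed SE sits at float-rounding level — could never expand across
    its true low-slope region.

    ``x`` must be the time-ordered primary sweep of a single loading limb
    (monotone in primary up to actuator resolution).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < window:
        raise ValueError(f"curve has {n} points; neutral-zone window needs {window}")
    if window < 3:
        raise ValueError("window must be >= 3")
    slopes = _window_slopes(x, y, window)
    abs_slopes = np.abs(slopes)
    minimum = abs_slopes.min()
    ties = np.flatnonzero(abs_slopes == minimum)
    if ties.size > 1:
        zero_cross = int(np.argmin(np.abs(y)))
        centre_dist = np.abs(ties + (window - 1) / 2.0 - zero_cross)
        ties = ties[centre_dist == centre_dist.min()]
    start = int(ties[0])
    lo, hi = start, start + window - 1
    _, seed_se, seed_sxx = _ols(x[lo:hi + 1], y[lo:hi + 1], se_kind)
    if resolution is None:
        resolution = 1e-3 * float(np.ptp(y))
    res_floor = resolution / math.sqrt(12.0)    # RMS of quantization error
    d2 = np.diff(y, 2)
    noise_floor = float(np.median(np.abs(d2))) / (0.6745 * math.sqrt(6.0)) \
        if d2.size else 0.0
    floor = max(res_floor, noise_floor)
    if se_kind == "slope" and seed_sxx > 0:
        floor = floor / math.sqrt(seed_sxx)
    threshold = (1.0 + se_growth) * max(seed_se, floor)

    def _se(a: int, b: int) -> float:
        return _ols(x[a:b + 1], y[a:b + 1], se_kind)[1]

    # alternate sides; a side rejected now may pass later once the other
    # side has grown, so stop only when neither side can be extended
    take_left = True
    while True:
        moved = False
        for _attempt in range(2):
            if take_left and lo > 0:
                cand = (lo - 1, hi)
            elif not take_left and hi < n - 1:
                cand = (lo, hi + 1)
            else:
                take_left = not take_left
                continue
            if _se(*cand) <= threshold:
                lo, hi = cand
                moved = True
                take_left = not take_left
                break
            take_left = not take_left
        if not moved:
            break
    slope, se, _ = _ols(x[lo:hi + 1], y[lo:hi + 1], se_kind)
    return NeutralZoneRegion(start=lo, end=hi, slope=slope, slope_se=se,
                             seed_se=seed_se,
                             length=float(np.ptp(x[lo:hi + 1])), limb=limb)


def _neutral_zone_over_limbs(segment: CycleSegment, limbs: tuple[str, str],
                             window: int, se_growth: float,
                             se_kind: str) -> NeutralZoneRegion:
    """NZ search over the loading traversal: best region across both loading
    limbs (each region confined to a single limb)."""
    regions = []
    for limb in limbs:
        x, y = segment.loading_limb(limb)
        if x.size >= window:
            regions.append(find_neutral_zone(x, y, window, se_growth, se_kind, limb=limb))
    if not regions:
        raise ValueError("no loading limb long enough for the neutral-zone window")
    return min(regions, key=lambda r: (abs(r.slope), r.limb))


# --------------------------------------------------------------------------
# assembled parameter sets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AxialParameters:
    """The five axial outcomes of one cyclic test."""

    range_of_motion: float       # mm
    compressive_stiffness: float  # N/mm
    tensile_stiffness: float      # N/mm
    nz_length: float              # mm
    nz_stiffness: float           # N/mm
    nz_region: NeutralZoneRegion | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.range_of_motion < 0:
            raise ValueError("range_of_motion must be >= 0")
        if self.nz_length > self.range_of_motion * (1 + 1e-12):
            raise ValueError("nz_length cannot exceed range_of_motion")
        for name in ("compressive_stiffness", "tensile_stiffness", "nz_stiffness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("range_of_motion", "compressive_stiffness", "tensile_stiffness",
                 "nz_length", "nz_stiffness")}


@dataclass(frozen=True)
class TorsionalParameters:
    """The torsional outcomes of one cyclic test; ``torsional_stiffness`` is
    the clockwise/counterclockwise average."""

    torsional_stiffness: float   # N·mm/deg
    cw_stiffness: float
    ccw_stiffness: float
    torque_range: float          # N·mm
    nz_length: float             # degrees
    nz_stiffness: float          # N·mm/deg
    nz_region: NeutralZoneRegion | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.torque_range < 0:
            raise ValueError("torque_range must be >= 0")
        expected = 0.5 * (self.cw_stiffness + self.ccw_stiffness)
        if not math.isclose(self.torsional_stiffness, expected, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("torsional_stiffness must equal the cw/ccw average")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("torsional_stiffness", "cw_stiffness", "ccw_stiffness",
                 "torque_range", "nz_length", "nz_stiffness")}


def axial_parameters(segment: CycleSegment, window: int = 15,
                     se_growth: float = 0.10, fraction: float = 0.20,
                     se_kind: str = "residual") -> AxialParameters:
    """All five axial parameters of the final cycle.

    The neutral zone is searched over the loading traversal spanning the
    compressive and tensile limbs; its primary-axis extent and slope give
    the NZ length and NZ stiffness.
    """
    nz = _neutral_zone_over_limbs(segment, ("compressive", "tensile"),
                                  window, se_growth, se_kind)
    return AxialParameters(
        range_of_motion=range_of_motion(segment),
        compressive_stiffness=limb_stiffness(segment, "compressive", fraction),
        tensile_stiffness=limb_stiffness(segment, "tensile", fraction),
        nz_length=nz.length,
        nz_stiffness=nz.stiffness,
        nz_region=nz,
    )


def torsional_parameters(segment: CycleSegment, window: int = 15,
                         se_growth: float = 0.10, fraction: float = 0.20,
                         se_kind: str = "residual",
                         torque_range_limb: str = "loading") -> TorsionalParameters:
    """All torsional parameters of the final cycle.

    Torque range is the total torque developed between the +amplitude and
    −amplitude endpoints of the last cycle, read from the loading limbs by
    default (``torque_range_limb="unloading"`` swaps the endpoints to the
    opposite traversal).
    """
    if segment.series.kind != TORSION:
        warnings.warn("torsional_parameters applied to a non-torsion record",
                      stacklevel=2)
    cw = limb_stiffness(segment, "cw", fraction)
    ccw = limb_stiffness(segment, "ccw", fraction)
    resp = segment.series.response
    if torque_range_limb == "loading":
        # ccw loading ends at +amplitude (closing peak); cw loading ends at −amplitude
        t_range = abs(float(resp[segment.end] - resp[segment.trough]))
    elif torque_range_limb == "unloading":
        t_range = abs(float(resp[segment.start] - resp[segment.trough]))
    else:
        raise ValueError("torque_range_limb must be 'loading' or 'unloading'")
    nz = _neutral_zone_over_limbs(segment, ("cw", "ccw"), window, se_growth, se_kind)
    return TorsionalParameters(
        torsional_stiffness=0.5 * (cw + ccw),
        cw_stiffness=cw,
        ccw_stiffness=ccw,
        torque_range=t_range,
        nz_length=nz.length,
        nz_stiffness=nz.stiffness,
        nz_region=nz,
    )
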