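"""Compression-to-failure ramp analysis: effective stress, peak, mode.

Failure strength is the effective stress (force over disc cross-sectional
area) at the characteristic peak of the stress-displacement curve.  The
peak is identified operationally as the first local stress maximum followed
by a relative drop of at least ``drop_threshold`` before the stress next
recovers; herniation (nucleus extrusion) and endplate fracture are
distinguished by whether stress re-rises after the drop.  The mode call is
a curve-shape heuristic — the laboratory ground truth is visual — and is
flagged as such in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import MechanicalTimeSeries

__all__ = ["FailureResult", "effective_stress", "detect_failure"]

HERNIATION = "herniation"
ENDPLATE = "endplate"
NONE_DETECTED = "none_detected"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class FailureResult:
    """Outcome of one ramp-to-failure test.

    ``failure_strength`` is in MPa and equals the effective stress at
    ``peak_index``; ``drop_fraction`` is the observed relative stress drop
    after the peak.  ``mode`` is ``"herniation"``, ``"endplate"`` or
    ``"none_detected"``; when classification was requested the call is
    heuristic (``classified=True`` marks it).
    """

    failure_strength: float | None
    failure_mode: str
    peak_index: int | None
    drop_fraction: float | None
    classified: bool = False

    def __post_init__(self) -> None:
        if self.failure_mode not in (HERNIATION, ENDPLATE, NONE_DETECTED, UNCLASSIFIED):
            raise ValueError(f"unknown failure mode {self.failure_mode!r}")
        if self.failure_mode != NONE_DETECTED:
            if self.failure_strength is None or self.failure_strength <= 0:
                raise ValueError("failure_strength must be positive when a mode is detected")
            if self.peak_index is None:
                raise ValueError("peak_index required when a mode is detected")


def effective_stress(force: float, area: float) -> float:
    """Effective stress in MPa: force (N) over cross-sectional area (mm²)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return force / area


def detect_failure(ramp: MechanicalTimeSeries, area: float,
                   drop_threshold: float = 0.10, classify: bool = True,
                   smooth_window: int = 5, rebound_margin: float = 0.05,
                   min_peak_fraction: float = 0.10) -> FailureResult:
    """Find the failure peak of a ramp and (optionally) classify the mode.

    The force channel is converted to effective stress and smoothed with a
    centred ``smooth_window``-sample moving mean (1 disables).  The failure
    peak is the first local maximum whose stress subsequently drops by at
    least ``drop_threshold`` (relative) before exceeding the peak again.
    Classification: herniation if the post-drop stress re-rises by more than
    ``rebound_margin`` of the peak (soft-tissue extrusion lets the segment
    re-load as the endplates approach); endplate otherwise (brittle terminal
    drop).  Reported strength is read from the unsmoothed stress record at
    the peak index.

    Peaks below ``min_peak_fraction`` of the record's maximum stress are
    ignored: relative drops are meaningless around zero load, so noise
    wiggles on the ramp toe would otherwise qualify.
    """
    if not (0.0 < drop_threshold < 1.0):
        raise ValueError("drop_threshold must be in (0, 1)")
    d = ramp.primary
    if np.any(np.diff(d) < 0):
        raise ValueError("failure ramp displacement must be monotone nondecreasing")
    stress_raw = ramp.response / area if area > 0 else None
    if stress_raw is None:
        raise ValueError("area must be positive")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(stress_raw, pad, mode="edge")
        stress = np.convolve(padded, kernel, mode="valid")[:stress_raw.size]
    else:
        stress = stress_raw

    peak = _first_qualifying_peak(stress, drop_threshold,
                                  min_peak_fraction * float(stress.max()))
    if peak is None:
        return FailureResult(None, NONE_DETECTED, None, None, classified=False)
    peak_idx, trough_idx, drop = peak
    strength = float(stress_raw[peak_idx])
    mode = UNCLASSIFIED
    if classify:
        tail = stress[trough_idx:]
        rebounds = tail.size > 1 and float(tail.max() - stress[trough_idx]) > \
            rebound_margin * stress[peak_idx]
        mode = HERNIATION if rebounds else ENDPLATE
    return FailureResult(strength, mode, int(peak_idx), float(drop),
                         classified=classify)


def _first_qualifying_peak(stress: np.ndarray, drop_threshold: float,
                           min_peak: float = 0.0):
    """First local max followed by a relative drop >= threshold before the
    stress next exceeds that max; returns (peak_idx, trough_idx, drop)."""
    n = stress.size
    i = 1
    while i < n - 1:
        if stress[i] >= stress[i - 1] and stress[i] > stress[i + 1]:
            peak_val = stress[i]
            if peak_val > max(min_peak, 0.0):
                j = i + 1
                running_min = peak_val
                running_min_idx = i
                while j < n:
                    if stress[j] < running_min:
                        running_min = stress[j]
                        running_min_idx = j
                    drop = (peak_val - running_min) / peak_val
                    if drop >= drop_threshold:
                        return i, running_min_idx, drop
                    if stress[j] > peak_val:
                        break
                    j += 1
        i += 1
    return None
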