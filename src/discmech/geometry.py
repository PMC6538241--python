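"""Disc height from digitized endplate maps, height loss, cross-section.

Bovine caudal endplates are convex, so disc height is not well defined by a
single caliper measurement; instead the superior and inferior endplates are
digitized from a sagittal radiograph as point polylines and the disc height
is the average vertical separation between them over their lateral overlap.
Disc-height loss after cyclic loading is reported as effective engineering
strain: axial deformation divided by initial disc height, in percent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EndplateProfile",
    "average_disc_height",
    "disc_height_loss",
    "cross_sectional_area",
    "DiscGeometry",
]


@dataclass(frozen=True)
class EndplateProfile:
    """Digitized endplate pair: (x, y) point arrays in pixels, plus scale.

    ``superior``/``inferior`` are (n, 2) arrays with strictly increasing x.
    ``scale`` converts pixels to mm.  The y axis must have a consistent
    orientation for both polylines (either image or cartesian convention);
    only the absolute separation is used.
    """

    superior: np.ndarray
    inferior: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        sup = np.asarray(self.superior, dtype=float)
        inf = np.asarray(self.inferior, dtype=float)
        for name, arr in (("superior", sup), ("inferior", inf)):
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"{name} polyline must be an (n>=2, 2) array")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"{name} polyline x-coordinates must be strictly increasing")
        if self.scale <= 0:
            raise ValueError("scale must be positive (mm per pixel)")
        object.__setattr__(self, "superior", sup)
        object.__setattr__(self, "inferior", inf)

    @property
    def overlap(self) -> tuple[float, float]:
        """Common lateral span of the two polylines, in pixels."""
        lo = max(self.superior[0, 0], self.inferior[0, 0])
        hi = min(self.superior[-1, 0], self.inferior[-1, 0])
        return lo, hi

    # ---------------------------------------------------------------- I/O
    def to_csv(self, superior_path: str | Path, inferior_path: str | Path,
               sidecar_path: str | Path | None = None) -> None:
        for path, arr in ((superior_path, self.superior), (inferior_path, self.inferior)):
            pd.DataFrame(arr, columns=["x_px", "y_px"]).to_csv(path, index=False)
        if sidecar_path is not None:
            Path(sidecar_path).write_text(json.dumps({"scale_mm_per_px": self.scale}))

    @classmethod
    def from_csv(cls, superior_path: str | Path, inferior_path: str | Path,
                 scale: float | None = None,
                 sidecar_path: str | Path | None = None) -> "EndplateProfile":
        if scale is None:
            if sidecar_path is None:
                raise ValueError("provide scale directly or via a JSON sidecar")
            scale = json.loads(Path(sidecar_path).read_text())["scale_mm_per_px"]
        read = lambda p: pd.read_csv(p)[["x_px", "y_px"]].to_numpy()
        return cls(read(superior_path), read(inferior_path), float(scale))


def average_disc_height(profile: EndplateProfile, n_grid: int = 1000) -> float:
    """Mean vertical separation between the endplates, in mm.

    Both polylines are linearly interpolated on a dense common x-grid over
    their lateral overlap; the height is the mean absolute vertical gap
    times the pixel scale.  The averaging itself accounts for the convex
    endplate curvature.
    """
    lo, hi = profile.overlap
    if hi <= lo:
        raise ValueError("endplate polylines have no lateral overlap")
    grid = np.linspace(lo, hi, n_grid)
    y_sup = np.interp(grid, profile.superior[:, 0], profile.superior[:, 1])
    y_inf = np.interp(grid, profile.inferior[:, 0], profile.inferior[:, 1])
    return float(np.mean(np.abs(y_sup - y_inf)) * profile.scale)


def disc_height_loss(initial_height: float, end_of_test_axial_deformation: float) -> float:
    """Disc-height loss as effective engineering strain, in percent.

    ``end_of_test_axial_deformation`` is the actuator displacement at the
    final sample of cyclic loading relative to the post-preload reference
    position; positive deformation = height loss.
    """
    if initial_height <= 0:
        raise ValueError("initial_height must be positive")
    return 100.0 * end_of_test_axial_deformation / initial_height


def cross_sectional_area(diameter: float, diameter2: float | None = None) -> float:
    """Disc cross-sectional area in mm².

    Circular by default (caudal discs are near-circular): π(d/2)².  Pass a
    second diameter for the elliptical variant π·d1·d2/4.
    """
    if diameter <= 0 or (diameter2 is not None and diameter2 <= 0):
        raise ValueError("diameters must be positive")
    if diameter2 is None:
        diameter2 = diameter
    return math.pi * diameter * diameter2 / 4.0


@dataclass(frozen=True)
class DiscGeometry:
    """Specimen geometry: diameter (mm), cross-sectional area (mm²),
    initial disc height (mm)."""

    diameter: float
    initial_height: float
    cross_sectional_area: float | None = None

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.initial_height <= 0:
            raise ValueError("diameter and initial_height must be positive")
        area = self.cross_sectional_area
        if area is None:
            area = cross_sectional_area(self.diameter)
            object.__setattr__(self, "cross_sectional_area", area)
        elif area <= 0:
            raise ValueError("cross_sectional_area must be positive")
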