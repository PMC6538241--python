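"""Raw actuator records from servohydraulic motion-segment tests.

A :class:`MechanicalTimeSeries` holds one test channel pair: time plus the
controlled primary axis (axial displacement in mm or rotation in degrees)
and the measured response (force in N or torque in N·mm).  Sign convention
throughout the package: tension and counterclockwise rotation are positive;
compression and clockwise rotation are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MechanicalTimeSeries", "AXIAL", "TORSION"]

AXIAL = "axial"
TORSION = "torsion"

_COLUMNS = {
    AXIAL: ("time_s", "displacement_mm", "force_N"),
    TORSION: ("time_s", "rotation_deg", "torque_Nmm"),
}


@dataclass(frozen=True)
class MechanicalTimeSeries:
    """One mechanical test record.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing.
    primary : ndarray
        Controlled axis: axial displacement (mm) or rotation (degrees).
    response : ndarray
        Measured load: force (N) or torque (N·mm).
    kind : str
        Channel tag, ``"axial"`` or ``"torsion"``.  Failure ramps use
        ``"axial"`` (displacement/force).
    """

    time: np.ndarray
    primary: np.ndarray
    response: np.ndarray
    kind: str = AXIAL
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.primary, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if not (t.shape == p.shape == r.shape) or t.ndim != 1:
            raise ValueError("time, primary and response must be equal-length 1-D arrays")
        if t.size < 30:
            raise ValueError(f"record too short ({t.size} samples, need >= 30)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.kind not in _COLUMNS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "primary", p)
        object.__setattr__(self, "response", r)

    def __len__(self) -> int:
        return self.time.size

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        cols = _COLUMNS[self.kind]
        return pd.DataFrame(dict(zip(cols, (self.time, self.primary, self.response))))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str | None = None) -> "MechanicalTimeSeries":
        """Read a test record, inferring the channel kind from the header."""
        df = pd.read_csv(path)
        if kind is None:
            for k, cols in _COLUMNS.items():
                if list(df.columns[:3]) == list(cols):
                    kind = k
                    break
            else:
                raise ValueError(
                    f"unrecognised columns {list(df.columns)}; expected one of "
                    f"{[list(c) for c in _COLUMNS.values()]}"
                )
        cols = _COLUMNS[kind]
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(),
                   df[cols[2]].to_numpy(), kind=kind)
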