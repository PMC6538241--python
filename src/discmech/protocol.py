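"""Loading-protocol and ground-truth parameter types for the simulator.

The default :class:`LoadingProtocol` reproduces the cyclic testing protocol
used for bovine caudal motion segments: a 0.1 MPa compressive preload,
20 axial cycles at 0.1 Hz between +0.25 MPa effective tension and
−0.50 MPa effective compression, ±4° torsion for 20 cycles at 0.1 Hz, and
a 2 mm/min ramp to failure.  Stress limits are effective stresses (force
over disc cross-sectional area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["LoadingProtocol", "CurveTruth", "FailureTruth", "CohortSpec"]


@dataclass(frozen=True)
class LoadingProtocol:
    """Cyclic + failure loading protocol applied to a motion segment.

    Units: stresses MPa, durations s, frequency Hz, rotation degrees,
    failure ramp rate mm/min.
    """

    preload_stress: float = 0.1          # MPa, compressive
    preload_duration: float = 300.0      # s
    n_cycles: int = 20
    frequency: float = 0.1               # Hz
    tension_limit: float = 0.25          # MPa, > 0
    compression_limit: float = -0.50     # MPa, < 0
    rotation_amplitude: float = 4.0      # degrees
    failure_rate: float = 2.0            # mm/min
    samples_per_cycle: int = 400

    def __post_init__(self) -> None:
        if not (self.tension_limit > 0 > self.compression_limit):
            raise ValueError("require tension_limit > 0 > compression_limit")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.samples_per_cycle < 50:
            raise ValueError(
                "samples_per_cycle must be >= 50 so each limb can hold the "
                "15-point neutral-zone window"
            )
        if self.frequency <= 0 or self.rotation_amplitude <= 0 or self.failure_rate <= 0:
            raise ValueError("frequency, rotation_amplitude and failure_rate must be positive")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


@dataclass(frozen=True)
class CurveTruth:
    """Analytically known parameters of a simulated hysteresis loop.

    The loading limbs follow a logistic-blended trilinear stiffness law:
    slope ``nz_stiffness`` inside the neutral zone
    (|x − nz_center| < nz_half_width), blending over a logistic transition
    of sharpness ``transition_sharpness`` (1/mm or 1/deg) into
    ``compressive_stiffness`` on the compression side and
    ``tensile_stiffness`` on the tension side.  For torsion the same fields
    are read as clockwise (compressive slot) and counterclockwise (tensile
    slot) stiffnesses in N·mm/deg.

    ``hysteresis_offset`` is the constant response gap between the loading
    and unloading limbs.  Defaults are representative of an intact bovine
    caudal disc.
    """

    nz_center: float = 0.0               # mm (or deg)
    nz_half_width: float = 0.30          # mm (or deg)
    nz_stiffness: float = 25.0           # N/mm (or N·mm/deg)
    compressive_stiffness: float = 220.0  # N/mm; torsion: cw N·mm/deg
    tensile_stiffness: float = 120.0      # N/mm; torsion: ccw N·mm/deg
    hysteresis_offset: float = 12.0      # N (or N·mm)
    noise_sd: float = 0.0                # N (or N·mm)
    transition_sharpness: float = 100.0  # 1/mm (or 1/deg)

    def __post_init__(self) -> None:
        if self.nz_stiffness < 0:
            raise ValueError("nz_stiffness must be >= 0")
        if self.compressive_stiffness < self.nz_stiffness:
            raise ValueError("compressive_stiffness must be >= nz_stiffness")
        if self.tensile_stiffness < self.nz_stiffness:
            raise ValueError("tensile_stiffness must be >= nz_stiffness")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.transition_sharpness <= 0:
            raise ValueError("transition_sharpness must be positive")
        if self.nz_half_width < 0:
            raise ValueError("nz_half_width must be >= 0")

    @property
    def transition_width(self) -> float:
        """10–90% width of one logistic blending transition (mm or deg)."""
        return math.log(81.0) / self.transition_sharpness

    @property
    def nz_length(self) -> float:
        """True neutral-zone extent on the primary axis."""
        return 2.0 * self.nz_half_width


@dataclass(frozen=True)
class FailureTruth:
    """Ground truth of a simulated compression-to-failure ramp.

    ``mode`` is ``"herniation"`` (nucleus extrusion: partial stress drop
    followed by a rebound as the endplates approach) or ``"endplate"``
    (brittle fracture: terminal drop, no rebound).
    """

    mode: str = "herniation"
    peak_stress: float = 2.0             # MPa
    peak_displacement: float = 3.0       # mm
    post_peak_drop_fraction: float = 0.40
    rebound: bool = True
    noise_sd: float = 0.0                # MPa, on stress

    def __post_init__(self) -> None:
        if self.mode not in ("herniation", "endplate"):
            raise ValueError("mode must be 'herniation' or 'endplate'")
        if self.peak_stress <= 0 or self.peak_displacement <= 0:
            raise ValueError("peak_stress and peak_displacement must be positive")
        if not (0.0 < self.post_peak_drop_fraction <= 1.0):
            raise ValueError("post_peak_drop_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one simulated experimental group.

    ``pct_change_mean``/``pct_change_sd`` give the per-specimen percent
    change applied to each intact baseline parameter (treated =
    intact × (1 + pct/100), pct ~ Normal(mean, sd)); ``intact_cv`` is the
    relative specimen-to-specimen scatter of the intact baselines.
    """

    group: str = "group"
    n: int = 10
    pct_change_mean: float = 0.0
    pct_change_sd: float = 0.0
    intact_cv: float = 0.0
    seed: int = 0
    per_parameter: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.pct_change_sd < 0 or self.intact_cv < 0:
            raise ValueError("spread parameters must be >= 0")
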