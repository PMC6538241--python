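"""End-to-end study orchestration on simulated cohorts.

Reproduces the paired-measurement structure of an ex vivo repair study:
every specimen is tested intact, then re-tested after a (simulated)
intervention, and each treated parameter is normalized to the same
specimen's intact value.  The cohort run is a pure function of
(design, protocol, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import simulate
from .cycles import (AxialParameters, TorsionalParameters, axial_parameters,
                     extract_last_cycle, torsional_parameters)
from .failure import FailureResult, detect_failure
from .geometry import average_disc_height, disc_height_loss
from .protocol import CurveTruth, FailureTruth, LoadingProtocol

__all__ = [
    "GroupDesign",
    "StudyDesign",
    "SpecimenRecord",
    "normalize_to_intact",
    "run_study",
    "cohort_table",
    "summarize_groups",
]

_TRUTH_FIELDS = {f for f in CurveTruth.__dataclass_fields__}


@dataclass(frozen=True)
class GroupDesign:
    """One experimental group and the truth perturbation it applies.

    ``axial_perturb``/``torsion_perturb`` map simulator truth fields (e.g.
    ``tensile_stiffness``, ``nz_half_width``) to mean percent change applied
    between the intact and treated test rounds; ``perturb_sd`` adds
    specimen-to-specimen normal scatter (percent) around those means.
    ``height_loss_pct`` is the simulated end-of-test axial deformation as a
    percent of disc height (mean, sd).
    """

    name: str
    n: int = 10
    axial_perturb: dict = field(default_factory=dict)
    torsion_perturb: dict = field(default_factory=dict)
    perturb_sd: float = 0.0
    height_loss_pct: tuple[float, float] = (8.0, 0.0)
    failure_truth: FailureTruth = field(default_factory=FailureTruth)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for d in (self.axial_perturb, self.torsion_perturb):
            unknown = set(d) - _TRUTH_FIELDS
            if unknown:
                raise ValueError(f"unknown truth fields in perturbation: {sorted(unknown)}")


@dataclass(frozen=True)
class StudyDesign:
    """Group table plus shared simulation conditions.

    ``intact_cv`` is the relative specimen-to-specimen scatter applied to
    the stiffness fields of the intact baseline truths; ``noise_sd_frac``
    is the measurement noise as a fraction of the response range.
    """

    groups: tuple[GroupDesign, ...]
    axial_truth: CurveTruth = field(default_factory=CurveTruth)
    torsion_truth: CurveTruth = field(default_factory=simulate.default_torsion_truth)
    intact_cv: float = 0.0
    noise_sd_frac: float = 0.0
    disc_height_mm: float = 8.0
    disc_diameter_mm: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")


@dataclass
class SpecimenRecord:
    """Paired intact/treated outcome of one simulated specimen."""

    specimen: str
    group: str
    intact_axial: AxialParameters | None = None
    treated_axial: AxialParameters | None = None
    intact_torsion: TorsionalParameters | None = None
    treated_torsion: TorsionalParameters | None = None
    ratios: dict = field(default_factory=dict)
    pct_change: dict = field(default_factory=dict)
    disc_height_mm: float | None = None
    disc_height_loss_pct: float | None = None
    failure: FailureResult | None = None
    error: str | None = None


def normalize_to_intact(intact: Mapping[str, float],
                        treated: Mapping[str, float]) -> tuple[dict, dict]:
    """Elementwise treated/intact ratios and percent changes.

    Keys must match.  An intact value of exactly 0 leaves that key's ratio
    undefined (NaN) without failing the rest of the set.
    """
    if set(intact) != set(treated):
        raise ValueError("intact and treated parameter keys must match")
    ratios, pct = {}, {}
    for key, iv in intact.items():
        if iv == 0:
            ratios[key] = math.nan
            pct[key] = math.nan
        else:
            r = treated[key] / iv
            ratios[key] = r
            pct[key] = 100.0 * (r - 1.0)
    return ratios, pct


def _perturbed(truth: CurveTruth, perturb: Mapping[str, float], sd: float,
               rng: np.random.Generator) -> CurveTruth:
    changes = {}
    for key, mean_pct in perturb.items():
        p = rng.normal(mean_pct, sd) if sd > 0 else mean_pct
        changes[key] = getattr(truth, key) * (1.0 + p / 100.0)
    return replace(truth, **changes) if changes else truth


def _jittered(truth: CurveTruth, cv: float, rng: np.random.Generator) -> CurveTruth:
    if cv <= 0:
        return truth
    fields = ("nz_stiffness", "compressive_stiffness", "tensile_stiffness")
    changes = {f: getattr(truth, f) * max(1.0 + cv * rng.standard_normal(), 0.05)
               for f in fields}
    return replace(truth, **changes)


def _with_noise(truth: CurveTruth, frac: float, span: float) -> CurveTruth:
    return replace(truth, noise_sd=frac * span) if frac > 0 else truth


def _analyze_pair(protocol: LoadingProtocol, truth: CurveTruth, seed: int,
                  kind: str, area: float):
    if kind == "axial":
        series = simulate.generate_axial_cycles(protocol, truth, seed, area)
        seg = extract_last_cycle(series, protocol.n_cycles, protocol.frequency)
        return series, axial_parameters(seg)
    series = simulate.generate_torsion_cycles(protocol, truth, seed)
    seg = extract_last_cycle(series, protocol.n_cycles, protocol.frequency)
    return series, torsional_parameters(seg)


def run_study(design: StudyDesign, protocol: LoadingProtocol | None = None,
              seed: int = 0, area_mm2: float | None = None) -> list[SpecimenRecord]:
    """Simulate and analyze a full cohort.

    Per specimen: generate intact axial + torsion records → extract
    parameters → perturb the underlying truth per the group design →
    generate and analyze the treated records → normalize treated/intact →
    simulate the radiographic height measurement and the terminal failure
    ramp.  A failed stage is recorded on the specimen and does not abort
    the cohort.
    """
    protocol = protocol or LoadingProtocol()
    if area_mm2 is None:
        from .geometry import cross_sectional_area
        area_mm2 = cross_sectional_area(design.disc_diameter_mm)
    records: list[SpecimenRecord] = []
    root = np.random.SeedSequence(seed)
    group_seqs = root.spawn(len(design.groups))
    axial_span = (protocol.tension_limit - protocol.compression_limit) * area_mm2
    for group, gseq in zip(design.groups, group_seqs):
        for i, sseq in enumerate(gseq.spawn(group.n)):
            rec = SpecimenRecord(specimen=f"{group.name}-{i + 1:03d}", group=group.name)
            rng = np.random.default_rng(sseq)
            seeds = [int(s) for s in
                     rng.integers(0, 2**31 - 1, size=4)]
            try:
                base_ax = _jittered(design.axial_truth, design.intact_cv, rng)
                base_to = _jittered(design.torsion_truth, design.intact_cv, rng)
                torsion_span = 2 * protocol.rotation_amplitude * \
                    0.5 * (base_to.compressive_stiffness + base_to.tensile_stiffness)
                ax_truth = _with_noise(base_ax, design.noise_sd_frac, axial_span)
                to_truth = _with_noise(base_to, design.noise_sd_frac, torsion_span)

                _, rec.intact_axial = _analyze_pair(protocol, ax_truth, seeds[0],
                                                    "axial", area_mm2)
                _, rec.intact_torsion = _analyze_pair(protocol, to_truth, seeds[1],
                                                      "torsion", area_mm2)

                ax_treated = _perturbed(ax_truth, group.axial_perturb,
                                        group.perturb_sd, rng)
                to_treated = _perturbed(to_truth, group.torsion_perturb,
                                        group.perturb_sd, rng)
                _, rec.treated_axial = _analyze_pair(protocol, ax_treated, seeds[2],
                                                     "axial", area_mm2)
                _, rec.treated_torsion = _analyze_pair(protocol, to_treated, seeds[3],
                                                       "torsion", area_mm2)

                intact = {**{f"axial_{k}": v for k, v in rec.intact_axial.as_dict().items()},
                          **{f"torsion_{k}": v for k, v in rec.intact_torsion.as_dict().items()}}
                treated = {**{f"axial_{k}": v for k, v in rec.treated_axial.as_dict().items()},
                           **{f"torsion_{k}": v for k, v in rec.treated_torsion.as_dict().items()}}
                rec.ratios, rec.pct_change = normalize_to_intact(intact, treated)

                # radiographic height and effective engineering strain
                profile = simulate.generate_endplate_profiles(
                    design.disc_height_mm, curvature_depth=0.8, scale=0.1,
                    seed=seeds[0] % (2**31 - 1))
                rec.disc_height_mm = average_disc_height(profile)
                hl_mean, hl_sd = group.height_loss_pct
                hl = rng.normal(hl_mean, hl_sd) if hl_sd > 0 else hl_mean
                deformation = hl / 100.0 * design.disc_height_mm
                rec.disc_height_loss_pct = disc_height_loss(rec.disc_height_mm, deformation)

                # terminal failure test on the treated state
                ramp = simulate.generate_failure_ramp(group.failure_truth, area_mm2,
                                                      seed=seeds[3])
                rec.failure = detect_failure(ramp, area_mm2)
            except Exception as exc:  # stage failure is per-specimen, not fatal
                rec.error = f"{type(exc).__name__}: {exc}"
            records.append(rec)
    return records


def cohort_table(records: list[SpecimenRecord]) -> pd.DataFrame:
    """Tidy cohort table: one row per specimen × normalized parameter."""
    rows = []
    for rec in records:
        if rec.error is not None:
            rows.append({"specimen": rec.specimen, "group": rec.group,
                         "parameter": "error", "intact": math.nan,
                         "treated": math.nan, "ratio": math.nan,
                         "pct_change": math.nan})
            continue
        intact = {**{f"axial_{k}": v for k, v in rec.intact_axial.as_dict().items()},
                  **{f"torsion_{k}": v for k, v in rec.intact_torsion.as_dict().items()}}
        treated = {**{f"axial_{k}": v for k, v in rec.treated_axial.as_dict().items()},
                   **{f"torsion_{k}": v for k, v in rec.treated_torsion.as_dict().items()}}
        for key in intact:
            rows.append({"specimen": rec.specimen, "group": rec.group,
                         "parameter": key, "intact": intact[key],
                         "treated": treated[key], "ratio": rec.ratios[key],
                         "pct_change": rec.pct_change[key]})
        rows.append({"specimen": rec.specimen, "group": rec.group,
                     "parameter": "disc_height_loss_pct", "intact": math.nan,
                     "treated": rec.disc_height_loss_pct, "ratio": math.nan,
                     "pct_change": math.nan})
        if rec.failure is not None and rec.failure.failure_strength is not None:
            rows.append({"specimen": rec.specimen, "group": rec.group,
                         "parameter": "failure_strength_MPa", "intact": math.nan,
                         "treated": rec.failure.failure_strength, "ratio": math.nan,
                         "pct_change": math.nan})
    return pd.DataFrame(rows)


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Group-wise mean ± sample SD of each parameter's normalized ratio
    (falling back to the treated value where no ratio is defined).

    Single-specimen groups report SD as NaN (undefined).  Inferential
    statistics are deliberately out of scope; this table is the hand-off
    point to any stats package.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    df = table.copy()
    df["value"] = df["ratio"].where(df["ratio"].notna(), df["treated"])
    out = (df.groupby(["group", "parameter"])["value"]
             .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
             .reset_index())
    return out
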