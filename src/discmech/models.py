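"""Model-object interface: build a test model from data, fit, summarize.

`AxialTest`, `TorsionTest` and `FailureTest` wrap one mechanical record
each; `fit()` returns a results object carrying the extracted parameters,
the neutral-zone region with its regression standard error, and quality
diagnostics, with `summary()` and `plot()` for reporting.
`StudySimulation` runs a whole simulated cohort and summarizes it.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import cycles, failure as failure_mod, study
from .protocol import LoadingProtocol
from .timeseries import MechanicalTimeSeries

__all__ = ["AxialTest", "TorsionTest", "FailureTest", "StudySimulation",
           "CyclicTestResults", "FailureTestResults", "StudyResults"]


class _CyclicTest:
    """Shared machinery of the axial and torsional test models."""

    kind = "axial"
    _analyze = staticmethod(cycles.axial_parameters)

    def __init__(self, data: MechanicalTimeSeries, window: int = 15,
                 se_growth: float = 0.10, fraction: float = 0.20,
                 se_kind: str = "residual", frequency: float | None = None,
                 test_id: str = "test"):
        self.data = data
        self.window = window
        self.se_growth = se_growth
        self.fraction = fraction
        self.se_kind = se_kind
        self.frequency = frequency
        self.test_id = test_id

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "_CyclicTest":
        kwargs.setdefault("test_id", Path(path).stem)
        return cls(MechanicalTimeSeries.from_csv(path), **kwargs)

    def fit(self) -> "CyclicTestResults":
        segment = cycles.extract_last_cycle(self.data, frequency=self.frequency)
        params = type(self)._analyze(segment, window=self.window,
                                     se_growth=self.se_growth,
                                     fraction=self.fraction, se_kind=self.se_kind)
        n_found = cycles.n_complete_cycles(self.data, self.frequency)
        return CyclicTestResults(self, segment, params, n_found)


class AxialTest(_CyclicTest):
    """Cyclic axial tension-compression test model.

    Fitting extracts range of motion, compressive and tensile stiffness
    (top-20% loading-portion regressions) and the neutral-zone length and
    stiffness (15-point minimal-slope window with 10% standard-error
    expansion) from the final loading cycle.
    """

    kind = "axial"
    _analyze = staticmethod(cycles.axial_parameters)


class TorsionTest(_CyclicTest):
    """Cyclic torsion test model: clockwise/counterclockwise stiffness and
    their average, torque range, and the torsional neutral zone."""

    kind = "torsion"
    _analyze = staticmethod(cycles.torsional_parameters)


class CyclicTestResults:
    """Fitted parameters of one cyclic test."""

    def __init__(self, model: _CyclicTest, segment: cycles.CycleSegment,
                 params, n_cycles_found: int):
        self.model = model
        self.segment = segment
        self.raw_params = params
        self.nz = params.nz_region
        self.n_cycles_found = n_cycles_found

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.raw_params.as_dict(), name=self.model.test_id)

    def to_record(self) -> dict:
        nz = self.nz
        return {
            "test_id": self.model.test_id,
            "kind": self.model.kind,
            "parameters": self.raw_params.as_dict(),
            "nz": {"start": nz.start, "end": nz.end, "limb": nz.limb,
                   "slope": nz.slope, "se": nz.slope_se},
            "qc": {"n_cycles_found": self.n_cycles_found,
                   "samples_per_cycle": int(round(len(self.model.data)
                                                  / max(self.n_cycles_found, 1)))},
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_record(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        units = {"axial": ("mm", "N/mm"), "torsion": ("deg", "N·mm/deg")}
        pu, su = units[self.model.kind]
        lines = [f"{type(self.model).__name__} results: {self.model.test_id}",
                 "=" * 46]
        for key, value in self.raw_params.as_dict().items():
            unit = pu if "length" in key or "motion" in key else (
                "N·mm" if key == "torque_range" else su)
            lines.append(f"{key:<24s} {value:12.4f}  {unit}")
        lines.append("-" * 46)
        lines.append(f"{'nz slope SE':<24s} {self.nz.slope_se:12.4g}  {su}")
        lines.append(f"{'nz window':<24s} [{self.nz.start}, {self.nz.end}]"
                     f" on {self.nz.limb} limb")
        lines.append(f"{'cycles found':<24s} {self.n_cycles_found:12d}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Final-cycle hysteresis loop with the neutral-zone region marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.segment.primary, self.segment.response, lw=1,
                label="final cycle")
        x, y = self.segment.loading_limb(self.nz.limb or "compressive")
        sl = slice(self.nz.start, self.nz.end + 1)
        ax.plot(x[sl], y[sl], lw=3, alpha=0.7, label="neutral zone")
        if self.model.kind == "axial":
            ax.set_xlabel("displacement (mm)")
            ax.set_ylabel("force (N)")
        else:
            ax.set_xlabel("rotation (deg)")
            ax.set_ylabel("torque (N·mm)")
        ax.legend()
        return ax


class FailureTest:
    """Compression-to-failure ramp model.

    Fitting converts force to effective stress, finds the characteristic
    failure peak (first local maximum followed by a relative stress drop of
    at least ``drop_threshold``) and heuristically classifies the failure
    mode from the post-drop behaviour.
    """

    def __init__(self, data: MechanicalTimeSeries, area_mm2: float,
                 drop_threshold: float = 0.10, smooth_window: int = 5,
                 classify: bool = True, test_id: str = "failure"):
        self.data = data
        self.area_mm2 = area_mm2
        self.drop_threshold = drop_threshold
        self.smooth_window = smooth_window
        self.classify = classify
        self.test_id = test_id

    @classmethod
    def from_csv(cls, path: str | Path, area_mm2: float, **kwargs) -> "FailureTest":
        kwargs.setdefault("test_id", Path(path).stem)
        return cls(MechanicalTimeSeries.from_csv(path, kind="axial"),
                   area_mm2, **kwargs)

    def fit(self) -> "FailureTestResults":
        res = failure_mod.detect_failure(self.data, self.area_mm2,
                                         self.drop_threshold, self.classify,
                                         self.smooth_window)
        return FailureTestResults(self, res)


class FailureTestResults:
    def __init__(self, model: FailureTest, result: failure_mod.FailureResult):
        self.model = model
        self.result = result

    @property
    def failure_strength(self):
        return self.result.failure_strength

    @property
    def failure_mode(self):
        return self.result.failure_mode

    def to_record(self) -> dict:
        return {"test_id": self.model.test_id, "area_mm2": self.model.area_mm2,
                **asdict(self.result)}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_record(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        r = self.result
        lines = [f"FailureTest results: {self.model.test_id}", "=" * 46]
        if r.failure_mode == failure_mod.NONE_DETECTED:
            lines.append("no qualifying failure peak detected")
        else:
            lines.append(f"{'failure strength':<24s} {r.failure_strength:10.4f}  MPa")
            lines.append(f"{'failure mode':<24s} {r.failure_mode:>10s}"
                         + ("  (heuristic)" if r.classified else ""))
            lines.append(f"{'post-peak drop':<24s} {100 * r.drop_fraction:10.1f}  %")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        stress = self.data_stress()
        ax.plot(self.model.data.primary, stress, lw=1)
        if self.result.peak_index is not None:
            i = self.result.peak_index
            ax.plot(self.model.data.primary[i], stress[i], "v", ms=8,
                    label=f"failure peak ({self.result.failure_mode})")
            ax.legend()
        ax.set_xlabel("displacement (mm)")
        ax.set_ylabel("effective stress (MPa)")
        return ax

    def data_stress(self):
        return self.model.data.response / self.model.area_mm2


class StudySimulation:
    """Whole-cohort simulation + analysis, statsmodels-style.

    ``run()`` simulates every specimen of the design (intact test, treated
    test, normalization, radiographic height, failure ramp) and returns a
    results object with the tidy cohort table and the group summary.
    """

    def __init__(self, design: study.StudyDesign,
                 protocol: LoadingProtocol | None = None, seed: int = 0):
        self.design = design
        self.protocol = protocol or LoadingProtocol()
        self.seed = seed

    def run(self) -> "StudyResults":
        records = study.run_study(self.design, self.protocol, self.seed)
        return StudyResults(self, records)


class StudyResults:
    def __init__(self, model: StudySimulation, records):
        self.model = model
        self.records = records
        self.table = study.cohort_table(records)

    def summary(self) -> pd.DataFrame:
        return study.summarize_groups(self.table)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)
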