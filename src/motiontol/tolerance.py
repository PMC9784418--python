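"""Motion-tolerance model: D95% vs added motion, fitted per patient.

This is the statistical core of the package, organised as a model /
results pair.  :class:`MotionToleranceModel` is built from a long-layout
table of raw motion-incorporated PTV D95% fractions (one row per patient,
waveform source and added-motion amplitude).  ``fit()``:

1. divides each patient's series by their control value (the native-4DCT
   plan's D95%), removing the simulation bias of the motion-incorporated
   technique (multiplicative control correction);
2. fits an unconstrained OLS quadratic of corrected D95% on added motion
   per (patient, source) series;
3. solves the first (95%) and second (90%) breaching points from each fit;
4. aggregates group means/SDs and, when tumor volumes are supplied,
   regresses breaching points on log volume.

Example
-------
>>> from motiontol import datasets, tolerance
>>> model = tolerance.MotionToleranceModel(datasets.load_d95_table(),
...                                        patient_meta=datasets.load_patient_table())
>>> res = model.fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breach import LogVolumeFit, QuadraticFit, fit_quadratic, fit_log_volume, solve_breach

__all__ = ["MotionToleranceModel", "MotionToleranceResults"]

_REQUIRED = ("patient", "source", "added_mm", "d95_raw")


class MotionToleranceModel:
    """D95%-vs-added-motion breaching model for a cohort of patients.

    Parameters
    ----------
    data
        Long-layout DataFrame with columns ``patient``, ``source``,
        ``added_mm``, ``d95_raw`` and optionally ``group``.
    patient_meta
        Optional per-patient DataFrame (column ``patient`` plus any of
        ``group``, ``gtv_cc``, ``itv_cc``) enabling grouped summaries and
        volume-trend fits.
    thresholds
        Breaching thresholds as fractions of prescription, decreasing.
    control_source, control_added_mm
        The series entry whose D95% defines the control correction.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        patient_meta: pd.DataFrame | None = None,
        thresholds: tuple[float, float] = (0.95, 0.90),
        control_source: str = "4DCT",
        control_added_mm: float = 0.0,
        design_max_mm: float | None = None,
    ) -> None:
        data = pd.DataFrame(data)
        missing = [c for c in _REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing required columns: {missing}")
        if not (0 < thresholds[1] < thresholds[0] < 1):
            raise ValueError("thresholds must be decreasing and strictly in (0, 1)")
        self.data = data.copy()
        self.patient_meta = None if patient_meta is None else pd.DataFrame(patient_meta)
        self.thresholds = tuple(thresholds)
        self.control_source = control_source
        self.control_added_mm = float(control_added_mm)
        self.design_max_mm = (
            float(data["added_mm"].max()) if design_max_mm is None else float(design_max_mm)
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "MotionToleranceModel":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, meta_path=None, **kwargs) -> "MotionToleranceModel":
        meta = None if meta_path is None else pd.read_csv(meta_path)
        return cls(pd.read_csv(path), patient_meta=meta, **kwargs)

    def _control_value(self, pdata: pd.DataFrame, patient) -> float:
        sel = pdata[
            (pdata["source"] == self.control_source)
            & (np.isclose(pdata["added_mm"], self.control_added_mm))
        ]
        if len(sel) != 1:
            raise ValueError(
                f"patient {patient}: expected exactly one control entry "
                f"({self.control_source}, {self.control_added_mm} mm), found {len(sel)}"
            )
        return float(sel["d95_raw"].iloc[0])

    def fit(self) -> "MotionToleranceResults":
        rows = []
        fits: dict[tuple, QuadraticFit] = {}
        for patient, pdata in self.data.groupby("patient", sort=True):
            control = self._control_value(pdata, patient)
            if control <= 0:
                raise ValueError(f"patient {patient}: non-positive control D95")
            for source, sdata in pdata.groupby("source", sort=True):
                sdata = sdata.sort_values("added_mm")
                x = sdata["added_mm"].to_numpy(dtype=float)
                y = sdata["d95_raw"].to_numpy(dtype=float) / control
                qf = fit_quadratic(x, y)
                fits[(patient, source)] = qf
                b1 = solve_breach(qf, self.thresholds[0], self.design_max_mm)
                b2 = solve_breach(qf, self.thresholds[1], self.design_max_mm)
                group = (
                    sdata["group"].iloc[0] if "group" in sdata.columns else "all"
                )
                rows.append(
                    {
                        "patient": patient,
                        "source": source,
                        "group": group,
                        "control_d95": control,
                        "a": qf.a,
                        "b": qf.b,
                        "c": qf.c,
                        "r2": qf.r2,
                        "x95_mm": b1.x,
                        "x90_mm": b2.x,
                        "x95_at_zero": b1.at_zero,
                        "x90_at_zero": b2.at_zero,
                        "x95_extrapolated": b1.extrapolated,
                        "x90_extrapolated": b2.extrapolated,
                    }
                )
        table = pd.DataFrame(rows)
        if self.patient_meta is not None:
            meta_cols = [
                c for c in ("group", "gtv_cc", "itv_cc") if c in self.patient_meta.columns
            ]
            meta = self.patient_meta[["patient"] + meta_cols].drop_duplicates("patient")
            if "group" in meta_cols:
                table = table.drop(columns="group")
            table = table.merge(meta, on="patient", how="left")
            if "group" not in table.columns:
                table["group"] = "all"
        return MotionToleranceResults(model=self, table=table, fits=fits)


@dataclass
class MotionToleranceResults:
    """Fitted breaching points, their fits, and cohort summaries."""

    model: MotionToleranceModel
    table: pd.DataFrame
    fits: dict = field(repr=False, default_factory=dict)

    def quadratic_fit(self, patient, source: str) -> QuadraticFit:
        return self.fits[(patient, source)]

    def group_summary(self) -> pd.DataFrame:
        """Mean and sample SD (n-1) of x95/x90/r2 per (group, source)."""
        rows = []
        for (group, source), g in self.table.groupby(["group", "source"], sort=True):
            row = {"group": group, "source": source, "n_patients": len(g)}
            for col in ("x95_mm", "x90_mm", "r2"):
                vals = g[col].dropna().to_numpy(dtype=float)
                row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
                row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
                row[f"{col}_n"] = len(vals)
            rows.append(row)
        return pd.DataFrame(rows)

    def volume_fits(self, volume_col: str = "gtv_cc") -> dict[str, LogVolumeFit]:
        """Log-volume fits of x95 and x90 per source (requires volumes)."""
        if volume_col not in self.table.columns:
            raise ValueError(f"no '{volume_col}' column; supply patient_meta with volumes")
        out = {}
        for source, g in self.table.groupby("source", sort=True):
            for col in ("x95_mm", "x90_mm"):
                pairs = g[[volume_col, col]].dropna()
                if len(pairs) >= 3:
                    out[f"{source}:{col}"] = fit_log_volume(
                        pairs[volume_col].to_numpy(), pairs[col].to_numpy()
                    )
        return out

    def to_csv(self, path) -> None:
        """Write the per-patient breach table (rounded for stable diffs)."""
        out = self.table.copy()
        for col in ("control_d95", "a", "b", "c", "r2", "x95_mm", "x90_mm"):
            out[col] = out[col].round(6)
        out.to_csv(path, index=False)

    def summary(self) -> str:
        """Human-readable report of breaching points and group statistics."""
        lines = ["Motion-tolerance breaching analysis", "=" * 60]
        lines.append(
            f"thresholds: {self.model.thresholds[0]:.0%} / {self.model.thresholds[1]:.0%}"
            f"   control: ({self.model.control_source}, "
            f"{self.model.control_added_mm:g} mm)"
        )
        lines.append("-" * 60)
        lines.append(f"{'patient':>7} {'source':>8} {'x95 mm':>8} {'x90 mm':>8} {'R^2':>7}  flags")
        for _, r in self.table.iterrows():
            flags = []
            if r.get("x95_at_zero"):
                flags.append("at-zero")
            if r.get("x95_extrapolated") or r.get("x90_extrapolated"):
                flags.append("extrapolated")
            lines.append(
                f"{r['patient']:>7} {r['source']:>8} "
                f"{_fmt(r['x95_mm']):>8} {_fmt(r['x90_mm']):>8} {r['r2']:>7.3f}  "
                + ",".join(flags)
            )
        lines.append("-" * 60)
        for _, r in self.group_summary().iterrows():
            lines.append(
                f"{r['group']:>12} {r['source']:>8}: "
                f"x95 {_fmt(r['x95_mm_mean'])} +- {_fmt(r['x95_mm_sd'])} mm, "
                f"x90 {_fmt(r['x90_mm_mean'])} +- {_fmt(r['x90_mm_sd'])} mm "
                f"(n={r['n_patients']})"
            )
        return "\n".join(lines)


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "-"
    return f"{v:.1f}"
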