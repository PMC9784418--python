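"""End-to-end delivery simulation for one case or a whole cohort.

Pipeline per case (the control-experiment design):

1. generate a conformal VMAT plan on the PTV (2-4 full arcs, 2 degree
   control points, equal MU weights);
2. deliver it statically, and normalize so the static PTV D95% = 100%;
3. deliver the 8 motion-incorporated variants (moving isocenter), scoring
   raw PTV D95% on the same normalization;
4. divide by the control plan's D95% (multiplicative correction) and fit
   breaching points with :class:`~motiontol.tolerance.MotionToleranceModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd
from scipy import stats

from .anatomy import Case
from .cohort import CohortSpec, experiment_matrix, sample_case
from .dose import BeamModel, deliver_static, deliver_with_motion
from .metrics import d95_from_dose, normalize_prescription
from .plans import VMATPlan, generate_conformal_arc
from .tolerance import MotionToleranceModel, MotionToleranceResults
from .waveforms import resample_to_control_points
from . import anatomy

__all__ = ["RunConfig", "CaseResult", "CohortResult", "make_plan", "simulate_case", "run_cohort"]


@dataclass(frozen=True)
class RunConfig:
    """Delivery-simulation settings.

    ``seconds_per_cp`` converts waveform time to control-point index (a
    0.33 s default approximates a one-minute full arc); the added-motion
    design points and breaching thresholds mirror the study design.
    """

    aperture_margin_mm: float = 5.0
    bev_pitch_mm: float = 2.5
    penumbra_sigma_mm: float = 3.0
    attenuation_mu: float = 0.0
    seconds_per_cp: float = 0.33
    anchor: str = "EXHALE_EXTREME"
    thresholds: tuple[float, float] = (0.95, 0.90)
    added_mm: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
    dvh_bins: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.thresholds[1] < self.thresholds[0] < 1):
            raise ValueError("thresholds must be decreasing and strictly in (0, 1)")
        if 0.0 not in self.added_mm:
            raise ValueError("added-motion design points must include 0")
        if self.seconds_per_cp <= 0:
            raise ValueError("seconds_per_cp must be positive")

    def beam(self) -> BeamModel:
        return BeamModel(
            penumbra_sigma=self.penumbra_sigma_mm, attenuation_mu=self.attenuation_mu
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat key=value config file (floats, tuples as csv)."""
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected key=value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in valid:
                    raise ValueError(f"{path}:{ln}: unknown key '{key}'")
                if key == "anchor":
                    kwargs[key] = val
                elif key in ("thresholds", "added_mm"):
                    kwargs[key] = tuple(float(v) for v in val.split(","))
                elif key == "dvh_bins":
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = float(val)
        return cls(**kwargs)


def _n_arcs_for(ptv_cc: float) -> int:
    if ptv_cc < 150.0:
        return 2
    if ptv_cc < 350.0:
        return 3
    return 4


def make_plan(case: Case, config: RunConfig = RunConfig()) -> VMATPlan:
    """Conformal full-arc VMAT plan targeting the case's PTV."""
    n_arcs = _n_arcs_for(anatomy.volume_cc(case.ptv))
    iso = case.grid.center()
    arc = generate_conformal_arc(
        case.ptv,
        iso,
        start_deg=0.0,
        stop_deg=358.0,
        aperture_margin_mm=config.aperture_margin_mm,
        bev_pitch=config.bev_pitch_mm,
    )
    return VMATPlan(arcs=[arc] * n_arcs, isocenter=iso)


@dataclass
class CaseResult:
    """Raw and corrected D95% of the 8 motion-incorporated plans."""

    case: Case
    plan: VMATPlan
    norm_factor: float
    table: pd.DataFrame  # patient, group, source, added_mm, d95_raw, d95_corrected

    @property
    def control_d95(self) -> float:
        sel = self.table[(self.table["source"] == "4DCT") & (self.table["added_mm"] == 0.0)]
        return float(sel["d95_raw"].iloc[0])


def simulate_case(case: Case, config: RunConfig = RunConfig()) -> CaseResult:
    """Simulate all motion-incorporated deliveries of one case.

    Deterministic for a given case (all randomness lives in the cohort
    sampling).  Dose is scored on the PTV only, which is what the D95%
    metric needs.
    """
    plan = make_plan(case, config)
    beam = config.beam()
    n_cp = plan.n_control_points()

    static = deliver_static(case.grid, plan, beam, score_mask=case.ptv)
    factor = normalize_prescription(static, case.ptv, config.dvh_bins)

    rows = []
    group = "SBRT" if case.is_sbrt else "conventional"
    for variant in experiment_matrix(case, config.added_mm, config.anchor):
        shifts = resample_to_control_points(variant.waveform, n_cp, config.seconds_per_cp)
        dose = deliver_with_motion(case.grid, plan, beam, shifts, score_mask=case.ptv)
        raw = factor * d95_from_dose(dose, case.ptv, config.dvh_bins)
        rows.append(
            {
                "patient": case.patient_id,
                "group": group,
                "source": variant.source,
                "added_mm": variant.added_mm,
                "d95_raw": raw,
                "is_control": variant.is_control,
            }
        )
    table = pd.DataFrame(rows)
    control = float(
        table.loc[(table["source"] == "4DCT") & (table["added_mm"] == 0.0), "d95_raw"].iloc[0]
    )
    table["d95_corrected"] = table["d95_raw"] / control
    return CaseResult(case=case, plan=plan, norm_factor=factor, table=table)


@dataclass
class CohortResult:
    """Cohort simulation output: per-case D95% tables plus the fitted model."""

    spec: CohortSpec
    config: RunConfig
    cases: list[CaseResult]
    d95_table: pd.DataFrame
    results: MotionToleranceResults

    def spearman_volume_x95(self, source: str = "4DCT") -> float:
        """Rank correlation between GTV volume and first breaching point."""
        t = self.results.table
        sel = t[t["source"] == source][["gtv_cc", "x95_mm"]].dropna()
        return float(stats.spearmanr(sel["gtv_cc"], sel["x95_mm"]).statistic)


def run_cohort(
    spec: CohortSpec,
    config: RunConfig = RunConfig(),
    continue_on_error: bool = False,
) -> CohortResult:
    """Sample and simulate a synthetic cohort, then fit breaching points.

    Failures propagate with the case id unless ``continue_on_error``.
    """
    case_results = []
    meta_rows = []
    for i in range(spec.n_patients):
        try:
            case = sample_case(spec, i)
            case_results.append(simulate_case(case, config))
            meta_rows.append(
                {
                    "patient": case.patient_id,
                    "group": "SBRT" if case.is_sbrt else "conventional",
                    "gtv_cc": anatomy.volume_cc(case.gtv),
                    "itv_cc": anatomy.volume_cc(case.itv),
                    "ptv_cc": anatomy.volume_cc(case.ptv),
                    "range_4dct_mm": case.meta.get("range_4dct_mm"),
                    "range_tr_mm": case.meta.get("range_tr_mm"),
                }
            )
        except Exception as e:  # pragma: no cover - guarded path
            if not continue_on_error:
                raise RuntimeError(f"case {i} failed: {e}") from e
    if not case_results:
        raise RuntimeError("no case simulated successfully")
    d95_table = pd.concat([cr.table for cr in case_results], ignore_index=True)
    meta = pd.DataFrame(meta_rows)
    model = MotionToleranceModel(
        d95_table,
        patient_meta=meta,
        thresholds=config.thresholds,
    )
    return CohortResult(
        spec=spec,
        config=config,
        cases=case_results,
        d95_table=d95_table,
        results=model.fit(),
    )
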