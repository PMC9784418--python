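"""DVH computation, D95% scoring and plan normalization/correction.

All doses are relative.  A case's static plan is normalized so the PTV
D95% equals 100% of prescription, and the same factor is reused for every
motion-incorporated delivery of that case.  The motion-incorporated plan
driven by the native 4DCT waveform acts as the control experiment: its
residual D95% deviation from 100% is a simulation bias, divided out of
the other motion plans of the same patient (multiplicative correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import StructureMask
from .dose import DoseGrid

__all__ = [
    "DVHCurve",
    "PlanScore",
    "compute_dvh",
    "d95",
    "d95_from_dose",
    "normalize_prescription",
    "apply_control_correction",
]


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of volume receiving at least each dose."""

    edges: np.ndarray
    cumvol: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        c = np.asarray(self.cumvol, dtype=float)
        if e.shape != c.shape or e.ndim != 1 or len(e) < 2:
            raise ValueError("edges and cumvol must be matching 1-D arrays")
        if np.any(np.diff(e) < 0) or np.any(np.diff(c) > 1e-12):
            raise ValueError("edges must be increasing and cumvol non-increasing")
        self.edges, self.cumvol = e, c


def compute_dvh(dose: DoseGrid, mask: StructureMask, n_bins: int = 1000) -> DVHCurve:
    """Cumulative DVH of ``dose`` over the voxels of ``mask``."""
    if not mask.voxels.any():
        raise ValueError(f"empty mask '{mask.label}'")
    vals = np.sort(dose.values[mask.voxels])
    vmax = vals[-1]
    if vmax <= 0:
        # no dose anywhere: the curve is a step at zero
        return DVHCurve(np.array([0.0, 0.0]), np.array([1.0, 0.0]))
    # bins span [0, vmax]; one extra edge nudged past the max makes the
    # curve end at exactly 0 without smearing the top of the spectrum
    edges = np.append(np.linspace(0.0, vmax, n_bins + 1), vmax * (1.0 + 1e-12))
    cumvol = 1.0 - np.searchsorted(vals, edges, side="left") / len(vals)
    return DVHCurve(edges, cumvol)


def d95(dvh: DVHCurve, volume_fraction: float = 0.95) -> float:
    """Largest dose received by at least ``volume_fraction`` of the volume.

    Linearly interpolated between DVH bins.
    """
    c, e = dvh.cumvol, dvh.edges
    below = np.nonzero(c < volume_fraction)[0]
    if len(below) == 0:
        return float(e[-1])
    i = below[0]
    if i == 0:
        return 0.0
    if c[i - 1] == c[i]:
        return float(e[i - 1])
    w = (c[i - 1] - volume_fraction) / (c[i - 1] - c[i])
    return float(e[i - 1] + w * (e[i] - e[i - 1]))


def d95_from_dose(
    dose: DoseGrid,
    mask: StructureMask,
    n_bins: int = 1000,
    volume_fraction: float = 0.95,
) -> float:
    return d95(compute_dvh(dose, mask, n_bins), volume_fraction)


def normalize_prescription(
    static_dose: DoseGrid, ptv: StructureMask, n_bins: int = 1000
) -> float:
    """Scale factor making the static plan's PTV D95% exactly 1.0.

    The factor (1 / raw D95%) defines the prescription dose scale for the
    case and must be reused unchanged for all its motion plans.
    """
    raw = d95_from_dose(static_dose, ptv, n_bins)
    if raw <= 0:
        raise ValueError("static plan PTV D95 is zero; cannot normalize")
    return 1.0 / raw


@dataclass
class PlanScore:
    """Raw and control-corrected D95% (fractions of prescription)."""

    d95_raw: float
    control_factor: float

    def __post_init__(self) -> None:
        if self.d95_raw <= 0 or self.control_factor <= 0:
            raise ValueError("d95_raw and control_factor must be positive")

    @property
    def d95_corrected(self) -> float:
        return self.d95_raw / self.control_factor


def apply_control_correction(raw_scores, control_d95: float) -> np.ndarray:
    """Divide raw D95% values by the control plan's D95%.

    The control (native-4DCT motion-incorporated) plan maps to exactly 1.0;
    the same factor corrects every other motion plan of the patient,
    including the free-breathing-waveform ones.
    """
    if control_d95 <= 0:
        raise ValueError("control_d95 must be positive")
    return np.asarray(raw_scores, dtype=float) / control_d95
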