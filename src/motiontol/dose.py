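"""Simplified dose engine: aperture projection with a Gaussian penumbra.

Each static field deposits, at a point with BEV coordinates (u, v) in the
(possibly shifted) beam frame,

    dose = MU x [aperture (*) Gaussian(sigma)](u, v) x exp(-mu_att * depth)

evaluated by bilinear interpolation of the convolved aperture fluence.
With sigma = 0 and mu_att = 0 the field is the exact aperture indicator,
which keeps a closed-form oracle available: shifting the isocenter is
identical to evaluating the unshifted field at translated points.

Motion-incorporated delivery displaces the beam isocenter opposite to the
tumor displacement at each control point, so scoring the static planning
structures emulates dose to a rigidly moving target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .anatomy import StructureMask, VoxelGrid
from .plans import ControlPoint, VMATPlan, beam_axes

__all__ = [
    "BeamModel",
    "DoseGrid",
    "field_dose",
    "deliver_static",
    "deliver_with_motion",
    "save_dose_nifti",
]


@dataclass(frozen=True)
class BeamModel:
    """Penumbra width (Gaussian sigma, mm) and optional attenuation (1/mm).

    Attenuation defaults to zero so dose is exactly translation-invariant;
    a positive value adds exponential falloff with depth along the beam.
    """

    penumbra_sigma: float = 3.0
    attenuation_mu: float = 0.0

    def __post_init__(self) -> None:
        if self.penumbra_sigma < 0 or self.attenuation_mu < 0:
            raise ValueError("penumbra_sigma and attenuation_mu must be >= 0")


@dataclass
class DoseGrid:
    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != tuple(self.grid.dims):
            raise ValueError("dose shape does not match grid dims")
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("dose must be finite and non-negative")
        self.values = v


def _fluence(cp: ControlPoint, sigma: float) -> np.ndarray:
    """Aperture convolved with the penumbra Gaussian (cached per cp)."""
    key = round(float(sigma), 9)
    cached = cp._fluence_cache.get(key)
    if cached is None:
        f = cp.aperture.astype(float)
        if sigma > 0:
            f = ndimage.gaussian_filter(f, sigma / cp.bev_pitch, mode="constant")
        cp._fluence_cache[key] = cached = f
    return cached


def _eval_field(
    points: np.ndarray,
    cp: ControlPoint,
    beam: BeamModel,
    iso: np.ndarray,
    iso_shift: np.ndarray,
    grid: VoxelGrid | None = None,
) -> np.ndarray:
    """Dose of one static field at arbitrary points, shape (n,)."""
    rel = points - (iso + iso_shift)
    _, eu, ev = beam_axes(cp.gantry_deg)
    u = rel @ eu
    v = rel @ ev
    flu = _fluence(cp, beam.penumbra_sigma)
    iu = (u - cp.bev_origin[0]) / cp.bev_pitch
    iv = (v - cp.bev_origin[1]) / cp.bev_pitch
    dose = cp.mu_weight * ndimage.map_coordinates(
        flu, [iu, iv], order=1, mode="constant", cval=0.0
    )
    if beam.attenuation_mu > 0 and grid is not None:
        d, _, _ = beam_axes(cp.gantry_deg)
        proj = points @ d
        corners = _grid_corners(grid) @ d
        dose = dose * np.exp(-beam.attenuation_mu * (proj - corners.min()))
    return dose


def _grid_corners(grid: VoxelGrid) -> np.ndarray:
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.dims) - 1) * grid.spacing
    return np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])


def field_dose(
    grid: VoxelGrid,
    cp: ControlPoint,
    beam: BeamModel,
    iso,
    iso_shift=(0.0, 0.0, 0.0),
) -> DoseGrid:
    """Dose of a single static field on the whole grid."""
    pts = grid.voxel_centers()
    vals = _eval_field(
        pts, cp, beam, np.asarray(iso, dtype=float), np.asarray(iso_shift, dtype=float), grid
    )
    return DoseGrid(grid, vals.reshape(grid.dims))


def _accumulate(
    grid: VoxelGrid,
    plan: VMATPlan,
    beam: BeamModel,
    shifts: np.ndarray,
    score_mask: StructureMask | None,
) -> DoseGrid:
    if score_mask is None:
        pts = grid.voxel_centers()
    else:
        if score_mask.grid != grid:
            raise ValueError("score mask lives on a different grid")
        pts = score_mask.points()
    total = np.zeros(pts.shape[0])
    for cp, s in zip(plan.control_points(), shifts):
        total += _eval_field(pts, cp, beam, plan.isocenter, s, grid)
    values = np.zeros(grid.dims)
    if score_mask is None:
        values = total.reshape(grid.dims)
    else:
        values[score_mask.voxels] = total
    return DoseGrid(grid, values)


def deliver_static(
    grid: VoxelGrid,
    plan: VMATPlan,
    beam: BeamModel,
    score_mask: StructureMask | None = None,
) -> DoseGrid:
    """Composite dose of the segmented plan with a fixed isocenter.

    ``score_mask`` optionally restricts evaluation to the voxels of one
    structure (dose is zero elsewhere), which is all a DVH needs and much
    faster on large grids.
    """
    shifts = np.zeros((plan.n_control_points(), 3))
    return _accumulate(grid, plan, beam, shifts, score_mask)


def deliver_with_motion(
    grid: VoxelGrid,
    plan: VMATPlan,
    beam: BeamModel,
    shifts: np.ndarray,
    score_mask: StructureMask | None = None,
) -> DoseGrid:
    """Composite dose with the isocenter displaced per control point.

    ``shifts`` holds the tumor displacement at each control point (one row
    per control point, arcs concatenated); the beam is shifted by the
    negated displacement so that scoring the static structures emulates a
    rigidly moving target.  An all-zero shift sequence reproduces
    :func:`deliver_static` bit-exactly.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.ndim == 1:
        shifts = np.column_stack([shifts, np.zeros_like(shifts), np.zeros_like(shifts)])
    if shifts.shape != (plan.n_control_points(), 3):
        raise ValueError(
            f"expected {plan.n_control_points()} control-point shifts, got {shifts.shape}"
        )
    return _accumulate(grid, plan, beam, -shifts, score_mask)


def save_dose_nifti(dose: DoseGrid, path) -> None:
    import nibabel as nib

    affine = np.diag([dose.grid.spacing] * 3 + [1.0])
    affine[:3, 3] = dose.grid.origin
    nib.save(nib.Nifti1Image(dose.values.astype(np.float32), affine), str(path))
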