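"""Voxelized target structures: GTV, CTV, ITV and PTV.

Structures live on an isotropic voxel grid in patient axes (SI, AP, LR),
voxel-center convention.  The standard target chain is

    CTV = GTV + microscopic-extension margin (2 mm SBRT / 7 mm conventional)
    ITV = union of the CTV translated along the breathing trajectory
    PTV = ITV + 5 mm isotropic setup margin

Margins are Euclidean-ball morphological dilations evaluated on voxel
centers; motion union uses nearest-voxel translation of the binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .waveforms import MotionWaveform

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "Case",
    "make_ellipsoid_gtv",
    "expand_margin",
    "build_itv",
    "volume_cc",
    "save_mask_nifti",
    "load_mask_nifti",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel grid: spacing (mm), dims and origin of voxel (0,0,0)."""

    spacing: float
    dims: tuple[int, int, int]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must each be >= 1")

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center coordinates, shape (prod(dims), 3), C order."""
        ax = [self.axis_coords(i) for i in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)

    def center(self) -> np.ndarray:
        return np.array(
            [self.origin[i] + (self.dims[i] - 1) * self.spacing / 2.0 for i in range(3)]
        )


@dataclass
class StructureMask:
    grid: VoxelGrid
    voxels: np.ndarray
    label: str = "GTV"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=bool)
        if v.shape != tuple(self.grid.dims):
            raise ValueError("mask shape does not match grid dims")
        self.voxels = v

    def points(self) -> np.ndarray:
        """Coordinates of occupied voxel centers, shape (n, 3)."""
        idx = np.argwhere(self.voxels)
        return np.asarray(self.grid.origin) + idx * self.grid.spacing

    def count(self) -> int:
        return int(self.voxels.sum())


def make_ellipsoid_gtv(
    grid: VoxelGrid, center, radii, label: str = "GTV"
) -> StructureMask:
    """Voxelize an ellipsoid: a voxel is included iff its center is inside."""
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    for i in range(3):
        lo, hi = grid.axis_coords(i)[0], grid.axis_coords(i)[-1]
        if center[i] - radii[i] < lo or center[i] + radii[i] > hi:
            raise ValueError(
                f"ellipsoid extends beyond grid along axis {i}: "
                f"[{center[i] - radii[i]:.2f}, {center[i] + radii[i]:.2f}] mm "
                f"vs grid [{lo:.2f}, {hi:.2f}] mm"
            )
    ax = [
        (grid.axis_coords(i) - center[i]) / radii[i] for i in range(3)
    ]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    return StructureMask(grid, x * x + y * y + z * z <= 1.0, label)


#: fraction of a voxel added to dilation radii to de-bias the voxel-center
#: criterion (boundary voxel centers sit on average ~0.3 voxel inside the
#: continuous structure surface, so raw center-to-center dilation erodes)
EDGE_COMPENSATION_VOX = 0.25


def expand_margin(m: StructureMask, margin_mm: float, label: str | None = None) -> StructureMask:
    """Dilate a mask by a Euclidean ball of radius ``margin_mm``.

    Voxel-center criterion with edge compensation: a voxel joins the
    expansion iff its center lies within ``margin_mm`` (plus a
    quarter-voxel de-biasing term, see ``EDGE_COMPENSATION_VOX``) of an
    occupied voxel center.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    label = label or m.label
    if margin_mm == 0 or not m.voxels.any():
        return StructureMask(m.grid, m.voxels.copy(), label)
    dist = ndimage.distance_transform_edt(
        ~m.voxels, sampling=[m.grid.spacing] * 3
    )
    out = dist <= margin_mm + EDGE_COMPENSATION_VOX * m.grid.spacing
    if _touches_boundary(out) and not _touches_boundary(m.voxels):
        raise ValueError(
            f"{margin_mm} mm expansion of '{m.label}' reaches the grid boundary"
        )
    return StructureMask(m.grid, out, label)


def _touches_boundary(v: np.ndarray) -> bool:
    return bool(
        v[0].any() or v[-1].any()
        or v[:, 0].any() or v[:, -1].any()
        or v[:, :, 0].any() or v[:, :, -1].any()
    )


def build_itv(ctv: StructureMask, w: MotionWaveform, label: str = "ITV") -> StructureMask:
    """Union of the target translated to every waveform displacement.

    Translations are rounded to whole voxels (binary masks, discrete
    workflow); for a rigid target this equals the union of per-phase
    targets whichever way the margin and the union are ordered.
    """
    spacing = ctv.grid.spacing
    shifts = np.unique(np.round(w.samples / spacing).astype(int), axis=0)
    idx = np.argwhere(ctv.voxels)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    out = np.zeros_like(ctv.voxels)
    for s in shifts:
        if np.any(lo + s < 0) or np.any(hi + s >= np.asarray(ctv.grid.dims)):
            raise ValueError(f"motion shift {s * spacing} mm pushes target outside grid")
        out |= _shift_mask(ctv.voxels, s)
    return StructureMask(ctv.grid, out, label)


def _shift_mask(v: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    out = np.zeros_like(v)
    src = []
    dst = []
    for ax, s in enumerate(shift_vox):
        n = v.shape[ax]
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = v[tuple(src)]
    return out


def volume_cc(m: StructureMask) -> float:
    """Structure volume in cm^3 (voxel count x spacing^3 / 1000)."""
    return m.count() * m.grid.spacing**3 / 1000.0


@dataclass
class Case:
    """A planning case: nested target structures, prescription and waveforms."""

    patient_id: str
    gtv: StructureMask
    ctv: StructureMask
    itv: StructureMask
    ptv: StructureMask
    ctv_margin_mm: float
    prescription: tuple[float, int]  # (cGy per fraction, n fractions)
    waveforms: dict[str, MotionWaveform] = field(default_factory=dict)
    is_sbrt: bool = False
    ptv_margin_mm: float = 5.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ctv_margin_mm not in (2.0, 7.0):
            raise ValueError("ctv_margin_mm must be 2 (SBRT) or 7 (conventional)")
        for inner, outer in ((self.gtv, self.ctv), (self.ctv, self.itv), (self.itv, self.ptv)):
            if np.any(inner.voxels & ~outer.voxels):
                raise ValueError(
                    f"structure nesting violated: {inner.label} not inside {outer.label}"
                )

    @property
    def grid(self) -> VoxelGrid:
        return self.gtv.grid


def build_case(
    patient_id: str,
    gtv: StructureMask,
    ctv_margin_mm: float,
    waveform_4dct: MotionWaveform,
    prescription: tuple[float, int],
    waveform_tr: MotionWaveform | None = None,
    is_sbrt: bool = False,
    ptv_margin_mm: float = 5.0,
    meta: dict | None = None,
) -> Case:
    """Assemble the GTV -> CTV -> ITV -> PTV chain for one patient.

    The ITV is always built from the 4DCT waveform (the planning-time
    motion estimate); the free-breathing waveform, when given, is carried
    for delivery simulation only.
    """
    ctv = expand_margin(gtv, ctv_margin_mm, label="CTV")
    itv = build_itv(ctv, waveform_4dct)
    ptv = expand_margin(itv, ptv_margin_mm, label="PTV")
    waveforms = {"4DCT": waveform_4dct}
    if waveform_tr is not None:
        waveforms["TR4DMRI"] = waveform_tr
    return Case(
        patient_id=patient_id,
        gtv=gtv,
        ctv=ctv,
        itv=itv,
        ptv=ptv,
        ctv_margin_mm=float(ctv_margin_mm),
        prescription=prescription,
        waveforms=waveforms,
        is_sbrt=is_sbrt,
        ptv_margin_mm=float(ptv_margin_mm),
        meta=meta or {},
    )


def save_mask_nifti(m: StructureMask, path) -> None:
    """Write a mask as NIfTI; the affine encodes spacing and origin."""
    import nibabel as nib

    affine = np.diag([m.grid.spacing] * 3 + [1.0])
    affine[:3, 3] = m.grid.origin
    nib.save(nib.Nifti1Image(m.voxels.astype(np.uint8), affine), str(path))


def load_mask_nifti(path, label: str = "GTV") -> StructureMask:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = float(img.affine[0, 0])
    grid = VoxelGrid(
        spacing=spacing,
        dims=tuple(int(d) for d in img.shape),
        origin=tuple(float(v) for v in img.affine[:3, 3]),
    )
    return StructureMask(grid, np.asanyarray(img.dataobj) > 0, label)
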