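import numpy as np
import pytest

from motiontol.anatomy import VoxelGrid, build_case, make_ellipsoid_gtv
from motiontol.plans import generate_conformal_arc, VMATPlan
from motiontol.waveforms import MotionWaveform


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def centered_grid(spacing: float, half_extent_mm: tuple[float, float, float]) -> VoxelGrid:
    dims = tuple(2 * int(np.ceil(h / spacing)) + 1 for h in half_extent_mm)
    origin = tuple(-(d - 1) * spacing / 2.0 for d in dims)
    return VoxelGrid(spacing=spacing, dims=dims, origin=origin)


@pytest.fixture
def coarse_grid():
    """Small isotropic grid centered on the origin (fast dose tests)."""
    return centered_grid(2.5, (50.0, 40.0, 40.0))


@pytest.fixture
def sphere_ptv(coarse_grid):
    return make_ellipsoid_gtv(coarse_grid, (0.0, 0.0, 0.0), (15.0, 15.0, 15.0), label="PTV")


@pytest.fixture
def short_arc_plan(sphere_ptv):
    """16-control-point arc on the spherical target (fast deliveries)."""
    arc = generate_conformal_arc(
        sphere_ptv, (0.0, 0.0, 0.0), start_deg=0.0, stop_deg=30.0, aperture_margin_mm=5.0
    )
    return VMATPlan(arcs=[arc], isocenter=np.zeros(3))


@pytest.fixture
def small_case():
    """A small, coarse SBRT-like case that simulates in about a second."""
    grid = centered_grid(2.5, (55.0, 40.0, 40.0))
    gtv = make_ellipsoid_gtv(grid, (0.0, 0.0, 0.0), (11.0, 10.0, 10.0))
    phase = np.zeros((10, 3))
    phase[:, 0] = 8.5 * (np.cos(np.pi * np.arange(10) / 10) ** 4)
    wf = MotionWaveform(np.tile(phase - phase.mean(axis=0), (2, 1)), dt=0.4, source="4DCT")
    tr = MotionWaveform(
        np.column_stack([np.sin(np.linspace(0, 60 * np.pi, 240)) * 5.0, np.zeros(240), np.zeros(240)]),
        dt=0.5,
        source="TR4DMRI",
    )
    return build_case(
        patient_id="TEST01",
        gtv=gtv,
        ctv_margin_mm=2.0,
        waveform_4dct=wf,
        waveform_tr=tr,
        prescription=(1200.0, 4),
        is_sbrt=True,
    )
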