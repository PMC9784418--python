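import numpy as np
import pytest

from motiontol.anatomy import VoxelGrid, make_ellipsoid_gtv
from motiontol.dose import BeamModel, DoseGrid, deliver_static, deliver_with_motion, field_dose
from motiontol.metrics import d95_from_dose
from motiontol.plans import ControlPoint, VMATPlan, generate_conformal_arc

from conftest import centered_grid


def disc_cp(radius_mm=15.0, pitch=2.5, gantry=0.0, n=25):
    """Circular aperture control point centered on the BEV origin."""
    half = (n - 1) / 2.0 * pitch
    u = np.linspace(-half, half, n)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    return ControlPoint(gantry, uu**2 + vv**2 <= radius_mm**2, (-half, -half), pitch, 1.0)


class TestFieldDose:
    def test_sharp_field_is_cylinder_indicator(self, coarse_grid):
        cp = disc_cp(radius_mm=15.0, gantry=0.0)
        beam = BeamModel(penumbra_sigma=0.0)
        dose = field_dose(coarse_grid, cp, beam, iso=(0, 0, 0))
        # geometric oracle: voxel in the beam iff its (u, v) = (SI, -AP)
        # coordinates fall inside the disc (gantry 0 beam runs along +AP)
        pts = coarse_grid.voxel_centers()
        u, v = pts[:, 0], pts[:, 2]
        inside = (u**2 + v**2 <= 15.0**2).reshape(coarse_grid.dims)
        # bilinear interpolation of the bitmap is exact except on pixel edges
        interior = np.abs(np.sqrt(u**2 + v**2).reshape(coarse_grid.dims) - 15.0) > 2.5 * 1.5
        np.testing.assert_array_equal(dose.values[interior], inside[interior].astype(float))

    def test_shift_equals_translated_evaluation(self, coarse_grid):
        cp = disc_cp(gantry=53.0)
        beam = BeamModel(penumbra_sigma=3.0)
        s = np.array([3.7, -2.1, 1.9])
        shifted = field_dose(coarse_grid, cp, beam, iso=(0, 0, 0), iso_shift=s)
        moved_grid = VoxelGrid(
            spacing=coarse_grid.spacing,
            dims=coarse_grid.dims,
            origin=tuple(np.asarray(coarse_grid.origin) - s),
        )
        reference = field_dose(moved_grid, cp, beam, iso=(0, 0, 0))
        np.testing.assert_allclose(shifted.values, reference.values, atol=1e-12)

    def test_penumbra_edge_is_half_open_field(self):
        # straight aperture edge: fluence at the geometric edge = 0.5
        n = 41
        ap = np.zeros((n, n), bool)
        ap[:, : n // 2 + 1] = True
        half = (n - 1) / 2.0 * 2.5
        cp = ControlPoint(0.0, ap, (-half, -half), 2.5, 1.0)
        grid = VoxelGrid(spacing=1.0, dims=(3, 3, 3), origin=(-1.0, -1.0, 1.25 - 1.0))
        beam = BeamModel(penumbra_sigma=4.0)
        dose = field_dose(grid, cp, beam, iso=(0, 0, 0))
        # central voxel sits exactly on the edge (v = +1.25 mm, half a pixel
        # past the last open pixel center)
        assert dose.values[1, 1, 1] == pytest.approx(0.5, abs=1e-6)


class TestDeliver:
    def test_single_field_plan_equals_field_dose(self, coarse_grid):
        cp = disc_cp(gantry=30.0)
        plan = VMATPlan(arcs=[[cp]], isocenter=np.zeros(3))
        beam = BeamModel()
        np.testing.assert_array_equal(
            deliver_static(coarse_grid, plan, beam).values,
            field_dose(coarse_grid, cp, beam, iso=np.zeros(3)).values,
        )

    def test_control_point_order_irrelevant(self, coarse_grid, short_arc_plan):
        beam = BeamModel()
        d1 = deliver_static(coarse_grid, short_arc_plan, beam)
        reversed_plan = VMATPlan(
            arcs=[list(reversed(short_arc_plan.arcs[0]))], isocenter=np.zeros(3)
        )
        d2 = deliver_static(coarse_grid, reversed_plan, beam)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_isocenter_dose_equals_per_field_resummation(self, coarse_grid, short_arc_plan):
        beam = BeamModel()
        total = deliver_static(coarse_grid, short_arc_plan, beam)
        c = np.asarray(coarse_grid.dims) // 2
        # independent per-field loop
        acc = 0.0
        for cp in short_arc_plan.control_points():
            acc += field_dose(coarse_grid, cp, beam, iso=np.zeros(3)).values[tuple(c)]
        assert total.values[tuple(c)] == pytest.approx(acc, rel=1e-12)

    def test_zero_waveform_reproduces_static_bit_exactly(self, coarse_grid, short_arc_plan):
        beam = BeamModel()
        static = deliver_static(coarse_grid, short_arc_plan, beam)
        moving = deliver_with_motion(
            coarse_grid, short_arc_plan, beam,
            np.zeros((short_arc_plan.n_control_points(), 3)),
        )
        np.testing.assert_array_equal(static.values, moving.values)

    def test_constant_shift_equals_translated_static(self, coarse_grid, short_arc_plan):
        # one-voxel SI shift: translation on the grid is exact
        beam = BeamModel()
        s = np.array([2.5, 0.0, 0.0])
        shifts = np.tile(s, (short_arc_plan.n_control_points(), 1))
        moving = deliver_with_motion(coarse_grid, short_arc_plan, beam, shifts)
        static = deliver_static(coarse_grid, short_arc_plan, beam)
        # beam moves by -s, so the dose pattern translates by -s: one voxel down
        translated = np.roll(static.values, -1, axis=0)
        translated[-1] = 0.0
        np.testing.assert_allclose(
            moving.values[1:-1], translated[1:-1], atol=1e-6 * static.values.max()
        )

    def test_shift_length_mismatch_rejected(self, coarse_grid, short_arc_plan):
        with pytest.raises(ValueError, match="control-point shifts"):
            deliver_with_motion(coarse_grid, short_arc_plan, BeamModel(), np.zeros((3, 3)))

    def test_huge_shift_collapses_target_coverage(self, coarse_grid, short_arc_plan, sphere_ptv):
        beam = BeamModel()
        shifts = np.tile([200.0, 0.0, 0.0], (short_arc_plan.n_control_points(), 1))
        dose = deliver_with_motion(coarse_grid, short_arc_plan, beam, shifts)
        assert dose.values.max() == 0.0

    def test_integral_dose_invariant_under_shifts(self, rng):
        # small aperture on a large grid: the whole kernel stays inside
        # both the grid and the bitmap (truncated tail must reach zero)
        grid = centered_grid(2.5, (60, 60, 60))
        cp = disc_cp(radius_mm=8.0, gantry=0.0, n=21)
        plan = VMATPlan(arcs=[[cp]], isocenter=np.zeros(3))
        beam = BeamModel(penumbra_sigma=3.0)
        ref = deliver_static(grid, plan, beam).values.sum()
        shifts = rng.uniform(-8, 8, size=(1, 3))
        out = deliver_with_motion(grid, plan, beam, shifts).values.sum()
        assert out == pytest.approx(ref, rel=1e-6)

    def test_additive_over_arcs(self, coarse_grid, sphere_ptv):
        arc = generate_conformal_arc(sphere_ptv, (0, 0, 0), 0.0, 20.0)
        beam = BeamModel()
        one = VMATPlan(arcs=[arc], isocenter=np.zeros(3))
        two = VMATPlan(arcs=[arc, arc], isocenter=np.zeros(3))
        shifts1 = np.tile([1.3, 0.0, -0.7], (one.n_control_points(), 1))
        shifts2 = np.tile([1.3, 0.0, -0.7], (two.n_control_points(), 1))
        d1 = deliver_with_motion(coarse_grid, one, beam, shifts1)
        d2 = deliver_with_motion(coarse_grid, two, beam, shifts2)
        np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-12)

    def test_score_mask_matches_full_grid(self, coarse_grid, short_arc_plan, sphere_ptv):
        beam = BeamModel()
        full = deliver_static(coarse_grid, short_arc_plan, beam)
        masked = deliver_static(coarse_grid, short_arc_plan, beam, score_mask=sphere_ptv)
        np.testing.assert_allclose(
            masked.values[sphere_ptv.voxels], full.values[sphere_ptv.voxels], atol=1e-12
        )
        assert np.all(masked.values[~sphere_ptv.voxels] == 0.0)


class TestDoseGridValidation:
    def test_negative_dose_rejected(self, coarse_grid):
        with pytest.raises(ValueError, match="non-negative"):
            DoseGrid(coarse_grid, -np.ones(coarse_grid.dims))
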