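import numpy as np
import pytest

from maskvar.errors import ConfigError, DataError
from maskvar.geometry import ContourPolygon, ContourSet
from maskvar.rasterize import (
    RasterStrategy,
    min_interior_subvoxels,
    point_in_polygon,
    rasterize,
    rasterize_centre,
    rasterize_supersampled,
    subvoxel_offsets_1d,
    subvoxel_offsets_3d,
    voxel_included,
)

from conftest import axis_aligned_geometry, square_contour
from oracles import dist_to_edges, random_simple_polygon, winding_number_inside

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)


class TestPointInPolygon:
    def test_interior_point(self):
        assert point_in_polygon([0.5, 0.5], UNIT_SQUARE) is True

    def test_exterior_point(self):
        assert point_in_polygon([2.0, 2.0], UNIT_SQUARE) is False

    def test_degenerate_polygon_rejected(self):
        line = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        with pytest.raises(DataError):
            point_in_polygon([0.5, 0.5], line)

    def test_matches_winding_number_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            poly = random_simple_polygon(rng)
            pts = rng.uniform(-7, 7, size=(200, 2))
            for p in pts:
                if dist_to_edges(p, poly) <= 1e-9:
                    continue
                assert point_in_polygon(p, poly) == winding_number_inside(p, poly)


class TestSubvoxelLattice:
    def test_single_split_gives_8_subvoxels_in_3d(self):
        assert subvoxel_offsets_3d(1).shape == (8, 3)

    def test_split_counts_double_per_axis(self):
        for split in range(4):
            assert len(subvoxel_offsets_1d(split)) == 2**split

    def test_offsets_symmetric_about_centre(self):
        for split in (1, 2, 3):
            off = subvoxel_offsets_1d(split)
            assert np.allclose(off, -off[::-1])
            assert np.all(np.abs(off) < 0.5)

    def test_quarter_threshold_needs_one_of_four(self):
        assert min_interior_subvoxels(25.0, 4) == 1

    def test_inclusive_threshold_comparison(self):
        assert voxel_included(1, 4, 25.0)
        assert not voxel_included(0, 4, 25.0)
        assert voxel_included(4, 4, 100.0)


class TestRasterizeCentre:
    def test_square_covers_nine_centres(self, unit_grid):
        # square spanning voxel centres (0..2, 0..2): oracle enumeration
        # of the 25 centres gives exactly the 3x3 block
        cset = square_contour(-0.5, 2.5)
        mask = rasterize_centre(cset, unit_grid)
        expected = np.zeros((5, 5, 1), dtype=bool)
        for r in range(5):
            for c in range(5):
                expected[r, c, 0] = winding_number_inside(
                    (r, c), [(-0.5, -0.5), (2.5, -0.5), (2.5, 2.5), (-0.5, 2.5)]
                )
        assert mask.n_voxels == 9
        assert np.array_equal(mask.voxels, expected)

    def test_empty_contour_set(self, unit_grid):
        mask = rasterize_centre(ContourSet(roi_name="empty"), unit_grid)
        assert mask.n_voxels == 0

    def test_subvoxel_polygon_catches_no_centre(self, unit_grid):
        cset = square_contour(0.1, 0.4)
        assert rasterize_centre(cset, unit_grid).n_voxels == 0

    def test_polygon_off_every_slice_plane_is_error(self, unit_grid):
        cset = square_contour(0, 2, z=3.0)
        with pytest.raises(DataError, match="z="):
            rasterize_centre(cset, unit_grid)

    def test_nested_polygons_make_a_hole(self, unit_grid):
        outer = square_contour(-0.5, 4.5).polygons[0]
        inner = square_contour(1.5, 2.5).polygons[0]
        cset = ContourSet(roi_name="ring", polygons=(outer, inner))
        mask = rasterize_centre(cset, unit_grid)
        assert mask.voxels[2, 2, 0] == False  # noqa: E712 - hole centre
        assert mask.voxels[0, 0, 0] == True  # noqa: E712
        assert mask.n_voxels == 25 - 1


def _ellipse_contour(rng, geometry):
    a, b = rng.uniform(3.0, 8.0, 2)
    cx, cy = rng.uniform(-1.0, 1.0, 2)
    phi = rng.uniform(0, np.pi)
    t = 2 * np.pi * np.arange(48) / 48
    x = cx + a * np.cos(t) * np.cos(phi) - b * np.sin(t) * np.sin(phi)
    y = cy + a * np.cos(t) * np.sin(phi) + b * np.sin(t) * np.cos(phi)
    z = np.zeros_like(x)
    verts = np.column_stack([x, y, z])
    return ContourSet("ellipse", (ContourPolygon(verts),)), np.pi * a * b, 2 * np.pi * max(a, b)


class TestRasterizeSupersampled:
    def test_half_covered_voxel_at_50_and_60_percent(self):
        # rectangle covering the low-row half of voxel (1,1): 2 of its 4
        # in-plane sub-voxel centres (offsets +/-0.25) are interior
        geom = axis_aligned_geometry(dims=(3, 3, 1))
        rect = np.array(
            [[-0.5, -0.5, 0], [1.0, -0.5, 0], [1.0, 2.5, 0], [-0.5, 2.5, 0]],
            dtype=float,
        )
        cset = ContourSet("rect", (ContourPolygon(rect),))
        inc = rasterize_supersampled(
            cset, geom, RasterStrategy("supersampled", 1, 50.0)
        )
        exc = rasterize_supersampled(
            cset, geom, RasterStrategy("supersampled", 1, 60.0)
        )
        assert inc.voxels[1, 1, 0] and inc.voxels[1, 0, 0]
        assert not exc.voxels[1, 1, 0]  # only 50% interior < 60%

    def test_full_threshold_mask_subset_of_lenient(self, unit_grid):
        cset = square_contour(-0.3, 2.2)
        strict = rasterize_supersampled(
            cset, unit_grid, RasterStrategy("supersampled", 1, 100.0)
        )
        lenient = rasterize_supersampled(
            cset, unit_grid, RasterStrategy("supersampled", 1, 12.5)
        )
        assert (strict.voxels <= lenient.voxels).all()

    def test_threshold_monotonicity_random_ellipses(self):
        geom = axis_aligned_geometry(dims=(21, 21, 1), origin=(-10, -10, 0))
        rng = np.random.default_rng(5)
        for _ in range(5):
            cset, _, _ = _ellipse_contour(rng, geom)
            prev = None
            for t in (10, 30, 50, 70, 90):
                m = rasterize_supersampled(
                    cset, geom, RasterStrategy("supersampled", 2, float(t))
                )
                if prev is not None:
                    assert (m.voxels <= prev).all()
                prev = m.voxels

    def test_split0_equals_centre_method(self):
        geom = axis_aligned_geometry(dims=(21, 21, 1), origin=(-10, -10, 0))
        rng = np.random.default_rng(6)
        cset, _, _ = _ellipse_contour(rng, geom)
        centre = rasterize_centre(cset, geom)
        for t in (10.0, 50.0, 100.0):
            ss0 = rasterize_supersampled(
                cset, geom, RasterStrategy("supersampled", 0, t)
            )
            assert np.array_equal(ss0.voxels, centre.voxels)

    def test_area_convergence_centre_method(self):
        geom = axis_aligned_geometry(dims=(25, 25, 1), origin=(-12, -12, 0))
        rng = np.random.default_rng(7)
        for _ in range(5):
            cset, area, perimeter = _ellipse_contour(rng, geom)
            m = rasterize_centre(cset, geom)
            # voxel area 1, voxel diagonal sqrt(2); polygon perimeter
            # bounds the boundary-voxel error band
            assert abs(m.n_voxels - area) <= perimeter * np.sqrt(2.0)

    def test_erosion_dilation_ordering(self):
        geom = axis_aligned_geometry(dims=(21, 21, 1), origin=(-10, -10, 0))
        rng = np.random.default_rng(8)
        for _ in range(5):
            cset, _, _ = _ellipse_contour(rng, geom)
            centre = rasterize_centre(cset, geom).voxels
            strict = rasterize_supersampled(
                cset, geom, RasterStrategy("supersampled", 1, 90.0)
            ).voxels
            lenient = rasterize_supersampled(
                cset, geom, RasterStrategy("supersampled", 1, 10.0)
            ).voxels
            assert (strict <= centre).all()
            assert (centre <= lenient).all()

    def test_nearest_plane_policy_runs(self, small_cohort):
        pat = small_cohort.patients[0]
        geom = pat.images["PET"].geometry
        strat = RasterStrategy("supersampled", 1, 50.0, z_policy="nearest_plane")
        m = rasterize(pat.contours["PET"], geom, strat)
        assert 0 < m.n_voxels < np.prod(geom.dims)


class TestStrategyValidation:
    def test_threshold_out_of_range(self):
        with pytest.raises(ConfigError):
            RasterStrategy("supersampled", 1, 0.0)
        with pytest.raises(ConfigError):
            RasterStrategy("supersampled", 1, 150.0)

    def test_unknown_method(self):
        with pytest.raises(ConfigError):
            RasterStrategy("mesh")
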