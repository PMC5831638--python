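"""Terrain and acoustic attribute operators against closed forms and
independent brute-force oracles."""

import numpy as np
import pytest
import shapely

from sedmap import terrain
from sedmap.grids import Grid

from conftest import brute_focal


def plane(a: float, b: float, c: float = 0.0, shape=(20, 20), cellsize=5.0) -> Grid:
    """z = a*x + b*y + c with x east, y north (map metres)."""
    g = Grid(np.zeros(shape), cellsize=cellsize, origin=(0.0, shape[0] * cellsize))
    xs, ys = g.cell_centers()
    return g.with_values(a * xs + b * ys + c)


class TestSlopeAspect:
    def test_flat_surface_zero_slope(self):
        s = terrain.slope(Grid(np.full((10, 10), -30.0), cellsize=5.0))
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "a,b,expected",
        [(0.1, 0.0, np.degrees(np.arctan(0.1))), (3.0, 4.0, np.degrees(np.arctan(5.0)))],
    )
    def test_plane_slope_closed_form(self, a, b, expected):
        s = terrain.slope(plane(a, b))
        np.testing.assert_allclose(s.values[1:-1, 1:-1], expected, atol=1e-9)

    @pytest.mark.parametrize(
        "a,b,east,north",
        [
            (-0.1, 0.0, 1.0, 0.0),  # descending eastward
            (0.0, -0.1, 0.0, 1.0),  # descending northward
            (0.1, 0.0, -1.0, 0.0),
        ],
    )
    def test_aspect_components_on_planes(self, a, b, east, north):
        e, n = terrain.aspect_components(plane(a, b))
        np.testing.assert_allclose(e.values[1:-1, 1:-1], east, atol=1e-12)
        np.testing.assert_allclose(n.values[1:-1, 1:-1], north, atol=1e-12)

    def test_flat_cells_zero_by_convention(self):
        e, n = terrain.aspect_components(Grid(np.zeros((8, 8)), cellsize=5.0))
        assert np.all(e.values == 0.0) and np.all(n.values == 0.0)

    def test_unit_circle_identity_or_zero(self, random_grid):
        e, n = terrain.aspect_components(random_grid)
        norm = e.values**2 + n.values**2
        valid = ~e.nodata_mask
        assert np.all(
            np.isclose(norm[valid], 1.0, atol=1e-12) | np.isclose(norm[valid], 0.0)
        )


class TestRDMV:
    def test_flat_neighborhood_zero(self):
        out = terrain.rdmv(Grid(np.full((6, 6), 2.0), cellsize=5.0))
        np.testing.assert_allclose(out.values, 0.0)

    def test_peak_centre_half(self):
        # 3x3 neighbourhood holding 0..8 with the centre at 8:
        # (8 - 4) / (8 - 0) = 0.5
        vals = np.array([[0.0, 1, 2], [3, 4, 5], [6, 7, 8]])
        vals[1, 1], vals[2, 2] = 8.0, 4.0
        out = terrain.rdmv(Grid(vals, cellsize=5.0))
        assert out.values[1, 1] == pytest.approx(0.5)

    def test_bounded(self, random_grid):
        out = terrain.rdmv(random_grid)
        valid = ~out.nodata_mask
        assert np.all(np.abs(out.values[valid]) <= 1.0 + 1e-12)


class TestStdev:
    def test_constant_zero(self):
        out = terrain.stdev(Grid(np.full((6, 6), 9.0), cellsize=5.0))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_one_to_nine_population_sd(self):
        out = terrain.stdev(Grid(np.arange(1.0, 10.0).reshape(3, 3), cellsize=5.0))
        assert out.values[1, 1] == pytest.approx(np.sqrt(60.0 / 9.0), abs=1e-9)

    def test_matches_oracle(self, random_grid):
        got = terrain.stdev(random_grid)
        want = brute_focal(random_grid.values, random_grid.nodata_mask, 3, "sd")
        valid = ~got.nodata_mask
        np.testing.assert_allclose(got.values[valid], want[valid], atol=1e-12)


class TestCurvatures:
    def test_planes_have_zero_curvature(self):
        for a, b in [(0.0, 0.0), (0.2, -0.1), (3.0, 4.0)]:
            curv, prof, plan = terrain.curvatures(plane(a, b, c=7.0))
            for g in (curv, prof, plan):
                np.testing.assert_allclose(g.values[1:-1, 1:-1], 0.0, atol=1e-9)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_bowl_and_dome_general_curvature(self, sign):
        c = 0.01
        g = Grid(np.zeros((21, 21)), cellsize=5.0, origin=(0.0, 105.0))
        xs, ys = g.cell_centers()
        x0, y0 = xs[10, 10], ys[10, 10]
        bowl = g.with_values(sign * c * ((xs - x0) ** 2 + (ys - y0) ** 2))
        curv, _, _ = terrain.curvatures(bowl)
        # bowl (sign +1) is concave: -400c; dome is +400c
        assert curv.values[10, 10] == pytest.approx(-sign * 400 * c, abs=1e-9)

    def test_profile_plan_zero_on_zero_gradient(self):
        curv, prof, plan = terrain.curvatures(Grid(np.zeros((6, 6)), cellsize=5.0))
        assert np.all(prof.values == 0.0) and np.all(plan.values == 0.0)


class TestBPI:
    def test_constant_zero(self):
        out = terrain.bpi(Grid(np.full((20, 20), 4.0), cellsize=5.0), 1, 4)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_linear_field_zero_at_interior(self):
        out = terrain.bpi(plane(0.3, -0.2, shape=(30, 30)), 1, 4)
        np.testing.assert_allclose(out.values[4:-4, 4:-4], 0.0, atol=1e-9)

    def test_peak_over_uniform_ring(self):
        vals = np.full((11, 11), 2.0)
        vals[5, 5] = 10.0
        out = terrain.bpi(Grid(vals, cellsize=5.0), 1, 2)
        assert out.values[5, 5] == pytest.approx(8.0)


class TestRugosity:
    def test_flat_exactly_one(self):
        area, rug = terrain.surface_area_and_rugosity(Grid(np.full((8, 8), 3.0), cellsize=5.0))
        np.testing.assert_allclose(rug.values, 1.0, atol=1e-12)
        np.testing.assert_allclose(area.values, 25.0, atol=1e-9)

    def test_tilted_plane_secant_rule(self):
        theta = np.radians(30.0)
        _, rug = terrain.surface_area_and_rugosity(plane(np.tan(theta), 0.0))
        np.testing.assert_allclose(rug.values[1:-1, 1:-1], 1.0 / np.cos(theta), atol=1e-3)

    def test_rough_surface_exceeds_one(self, random_grid):
        _, rug = terrain.surface_area_and_rugosity(random_grid)
        valid = ~rug.nodata_mask
        assert np.all(rug.values[valid] > 1.0)

    def test_rugosity_and_slope_co_monotone_on_planes(self):
        rugs = []
        for grad in (0.05, 0.15, 0.4):
            _, rug = terrain.surface_area_and_rugosity(plane(grad, 0.0))
            rugs.append(rug.values[5, 5])
        assert rugs[0] < rugs[1] < rugs[2]


class TestVRM:
    def test_flat_and_uniform_plane_zero(self):
        out = terrain.vrm(Grid(np.full((10, 10), 1.0), cellsize=5.0))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)
        out = terrain.vrm(plane(0.3, 0.1))
        np.testing.assert_allclose(out.values[2:-2, 2:-2], 0.0, atol=1e-12)

    def test_matches_normal_summation_oracle(self, rng):
        values = rng.normal(size=(15, 15))
        g = Grid(values, cellsize=5.0)
        got = terrain.vrm(g)

        # independent oracle: Horn gradient per cell (off-grid neighbours
        # take the centre value) -> unit normal -> 1 - |mean normal| over
        # the 3x3 neighbourhood (edge-shrunk)
        L = 5.0
        nr, nc = values.shape
        normals = np.zeros((nr, nc, 3))
        for i in range(nr):
            for j in range(nc):
                w = np.empty((3, 3))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < nr and 0 <= jj < nc:
                            w[1 + di, 1 + dj] = values[ii, jj]
                        else:
                            w[1 + di, 1 + dj] = values[i, j]
                dzdx = ((w[0, 2] + 2 * w[1, 2] + w[2, 2]) - (w[0, 0] + 2 * w[1, 0] + w[2, 0])) / (8 * L)
                dzdy = ((w[0, 0] + 2 * w[0, 1] + w[0, 2]) - (w[2, 0] + 2 * w[2, 1] + w[2, 2])) / (8 * L)
                grad = np.hypot(dzdx, dzdy)
                s = np.arctan(grad)
                if grad > 0:
                    normals[i, j] = [
                        np.sin(s) * (-dzdx) / grad,
                        np.sin(s) * (-dzdy) / grad,
                        np.cos(s),
                    ]
                else:
                    normals[i, j] = [0.0, 0.0, 1.0]
        want = np.zeros((nr, nc))
        for i in range(nr):
            for j in range(nc):
                sl = normals[max(0, i - 1) : i + 2, max(0, j - 1) : j + 2]
                mean = sl.reshape(-1, 3).mean(axis=0)
                want[i, j] = 1.0 - np.linalg.norm(mean)
        np.testing.assert_allclose(got.values, want, atol=1e-12)


class TestDeltaBackscatter:
    def test_constant_zero(self):
        out = terrain.delta_backscatter(Grid(np.full((6, 6), -25.0), cellsize=5.0))
        np.testing.assert_allclose(out.values, 0.0)

    def test_range_ten_db(self):
        vals = np.full((5, 5), -25.0)
        vals[2, 1], vals[2, 3] = -30.0, -20.0
        out = terrain.delta_backscatter(Grid(vals, cellsize=5.0))
        assert out.values[2, 2] == pytest.approx(10.0)

    def test_two_pass_composition_oracle(self, random_grid):
        got = terrain.delta_backscatter(random_grid)
        hi = brute_focal(random_grid.values, random_grid.nodata_mask, 3, "max")
        lo = brute_focal(random_grid.values, random_grid.nodata_mask, 3, "min")
        valid = ~got.nodata_mask
        np.testing.assert_allclose(got.values[valid], (hi - lo)[valid], atol=1e-12)
        assert np.all(got.values[valid] >= 0)


class TestDistanceFromCoast:
    def test_straight_coast_axis_aligned(self):
        g = Grid(np.zeros((10, 10)), cellsize=5.0, origin=(0.0, 50.0))
        coast = shapely.LineString([(0.0, 0.0), (0.0, 50.0)])  # west edge
        out = terrain.distance_from_coast(g, coast)
        # third column of cells: centres at x = 12.5
        np.testing.assert_allclose(out.values[:, 2], 12.5)

    def test_cell_on_coastline_zero(self):
        g = Grid(np.zeros((5, 5)), cellsize=5.0, origin=(0.0, 25.0))
        coast = shapely.LineString([(12.5, 0.0), (12.5, 25.0)])  # through col 2 centres
        out = terrain.distance_from_coast(g, coast)
        np.testing.assert_allclose(out.values[:, 2], 0.0, atol=1e-12)

    def test_matches_densified_vertex_oracle(self, rng):
        g = Grid(np.zeros((20, 20)), cellsize=5.0, origin=(0.0, 100.0))
        pts = np.column_stack(
            [np.linspace(-10, 110, 8), rng.uniform(-20, 0, size=8)]
        )
        coast = shapely.LineString(pts)
        out = terrain.distance_from_coast(g, coast)
        dense = np.asarray(
            [coast.interpolate(t, normalized=True).coords[0] for t in np.linspace(0, 1, 4000)]
        )
        xs, ys = g.cell_centers()
        d = np.min(
            np.hypot(xs.ravel()[:, None] - dense[None, :, 0], ys.ravel()[:, None] - dense[None, :, 1]),
            axis=1,
        ).reshape(g.shape)
        np.testing.assert_allclose(out.values, d, atol=0.5 * g.cellsize)

    def test_polygon_boundary_and_empty(self):
        g = Grid(np.zeros((4, 4)), cellsize=5.0, origin=(0.0, 20.0))
        with pytest.raises(ValueError, match="empty"):
            terrain.distance_from_coast(g, shapely.LineString())
        poly = shapely.box(-10.0, 0.0, 0.0, 20.0)
        out = terrain.distance_from_coast(g, poly)
        np.testing.assert_allclose(out.values[:, 0], 2.5)


class TestTranslationInvariance:
    def test_derivatives_unchanged_by_vertical_shift(self, random_grid):
        shifted = random_grid.with_values(random_grid.values + 123.4)
        pairs = [
            (terrain.slope(random_grid), terrain.slope(shifted)),
            (terrain.rdmv(random_grid), terrain.rdmv(shifted)),
            (terrain.stdev(random_grid), terrain.stdev(shifted)),
            (terrain.bpi(random_grid, 1, 4), terrain.bpi(shifted, 1, 4)),
            (terrain.vrm(random_grid), terrain.vrm(shifted)),
        ]
        e0, n0 = terrain.aspect_components(random_grid)
        e1, n1 = terrain.aspect_components(shifted)
        pairs += [(e0, e1), (n0, n1)]
        for a, b in pairs:
            valid = ~a.nodata_mask
            np.testing.assert_allclose(a.values[valid], b.values[valid], atol=1e-9)
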