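"""Wall reference space: resampling, distance fields, sublayers, thickness."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import wallstereo as ws
from wallstereo.wall_geometry import GeometryError, sublayer_of_f

from conftest import make_rect_region


class TestResamplePolyline:
    def test_uniform_subdivision_of_segment(self):
        seg = ws.BorderPolyline(np.array([[0.0, 0.0], [10.0, 0.0]]), role="inner")
        out = ws.resample_polyline(seg, 2.5)
        np.testing.assert_allclose(out.vertices[:, 0], [0, 2.5, 5, 7.5, 10])
        np.testing.assert_allclose(out.vertices[:, 1], 0)

    def test_spacing_beyond_length_keeps_endpoints(self):
        seg = ws.BorderPolyline(np.array([[0.0, 0.0], [3.0, 4.0]]), role="outer")
        out = ws.resample_polyline(seg, 100.0)
        np.testing.assert_allclose(out.vertices, [[0, 0], [3, 4]])

    def test_closed_square_walk(self):
        # brute-force arc-length walk on a closed square of side 10
        sq = ws.BorderPolyline(
            np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]),
            role="outer", closed=True,
        )
        out = ws.resample_polyline(sq, 1.0)
        v = out.vertices
        assert len(v) == 40
        # every vertex on the square boundary
        on_edge = (
            (np.isclose(v[:, 0], 0) | np.isclose(v[:, 0], 10))
            | (np.isclose(v[:, 1], 0) | np.isclose(v[:, 1], 10))
        )
        assert on_edge.all()
        gaps = np.hypot(*np.diff(np.vstack([v, v[:1]]), axis=0).T)
        assert (gaps <= 1.0 + 1e-9).all()

    def test_invalid_inputs(self):
        seg = ws.BorderPolyline(np.array([[0.0, 0.0], [1.0, 0.0]]), role="inner")
        with pytest.raises(GeometryError):
            ws.resample_polyline(seg, 0.0)
        with pytest.raises(GeometryError):
            degenerate = ws.BorderPolyline(
                np.array([[1.0, 1.0], [1.0, 1.0]]), role="inner"
            )
            ws.resample_polyline(degenerate, 1.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(-500, 500, allow_nan=False),
                st.floats(-500, 500, allow_nan=False),
            ),
            min_size=2, max_size=8, unique=True,
        ),
        st.floats(0.5, 50),
    )
    def test_resampling_preserves_curve(self, verts, spacing):
        arr = np.array(verts, dtype=float)
        if np.hypot(*np.diff(arr, axis=0).T).min() < 1e-6:
            return
        try:
            border = ws.BorderPolyline(arr, role="inner")
        except GeometryError:  # self-intersecting random chain
            return
        out = ws.resample_polyline(border, spacing)
        np.testing.assert_allclose(out.vertices[0], arr[0], atol=1e-9)
        np.testing.assert_allclose(out.vertices[-1], arr[-1], atol=1e-9)
        gaps = np.hypot(*np.diff(out.vertices, axis=0).T)
        assert (gaps <= spacing + 1e-6).all()
        # resampled vertices lie on the original curve
        dists = [border.as_shapely().distance(p) for p in
                 __import__("shapely").points(out.vertices)]
        assert max(dists) < 1e-6


class TestBuildWallRegion:
    def test_annular_wall_area(self, annulus):
        region, _ = annulus
        expected = np.pi * (1000.0**2 - 700.0**2)
        assert region.area_um2 == pytest.approx(expected, rel=1e-4)

    def test_rectangular_wall_area(self, rect_region):
        assert rect_region.area_um2 == pytest.approx(2000 * 700, rel=1e-9)

    def test_crossing_borders_rejected(self):
        inner = ws.BorderPolyline(
            np.array([[0.0, 0.0], [100.0, 100.0]]), role="inner"
        )
        outer = ws.BorderPolyline(
            np.array([[0.0, 100.0], [100.0, 0.0]]), role="outer"
        )
        with pytest.raises(GeometryError, match="intersect"):
            ws.build_wall_region(inner, outer, 1.0)

    def test_mismatched_topology_rejected(self):
        sq = ws.BorderPolyline(
            np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]),
            role="inner", closed=True,
        )
        open_b = ws.BorderPolyline(
            np.array([[-5.0, -5.0], [20.0, -5.0]]), role="outer"
        )
        with pytest.raises(GeometryError, match="topology"):
            ws.build_wall_region(sq, open_b, 1.0)

    def test_endcap_pairing_minimizes_cap_length(self):
        # inner chain given in reverse orientation still yields the rectangle
        x = np.linspace(0, 500, 11)
        outer = ws.BorderPolyline(
            np.column_stack([x, np.zeros_like(x)]), role="outer"
        )
        inner_rev = ws.BorderPolyline(
            np.column_stack([x[::-1], np.full_like(x, 200.0)]), role="inner"
        )
        region = ws.build_wall_region(inner_rev, outer, 1.0)
        assert region.area_um2 == pytest.approx(500 * 200, rel=1e-9)


class TestRelativePositionField:
    def test_annulus_midline_point(self, annulus, annulus_field):
        _, center = annulus
        pt = np.array([[center[0] + 850.0, center[1]]])
        row, col, _ = annulus_field.cell_index(pt)
        d1 = annulus_field.d1[row[0], col[0]]
        d2 = annulus_field.d2[row[0], col[0]]
        assert d1 == pytest.approx(150.0, abs=2.5)
        assert d2 == pytest.approx(150.0, abs=2.5)
        assert annulus_field.f_at(pt)[0] == pytest.approx(0.5, abs=0.01)
        assert annulus_field.sublayer_at(pt)[0] == ws.Sublayer.MIDDLE

    def test_annulus_two_thirds_boundary_is_inner(self, annulus, annulus_field):
        # radius 800: d1=200, d2=100 -> f=2/3, inner by the boundary rule
        _, center = annulus
        pt = np.array([[center[0], center[1] + 800.0]])
        assert annulus_field.f_at(pt)[0] == pytest.approx(2 / 3, abs=0.01)
        # the half-open threshold convention assigns f=2/3 to the inner layer
        assert sublayer_of_f(np.array([2 / 3]))[0] == ws.Sublayer.INNER
        # raster label always consistent with the cell's own f value
        row, col, _ = annulus_field.cell_index(pt)
        f_cell = annulus_field.f[row[0], col[0]]
        assert annulus_field.sublayer[row[0], col[0]] == sublayer_of_f(
            np.array([f_cell])
        )[0]

    def test_f_zero_on_outer_border(self, annulus_field):
        # cells adjacent to the outer border: f bounded by grid spacing
        m = annulus_field.mask
        fmin = annulus_field.f[m].min()
        fmax = annulus_field.f[m].max()
        assert fmin <= 1.5 * annulus_field.spacing / 300.0
        assert fmax >= 1 - 1.5 * annulus_field.spacing / 300.0
        assert fmin >= 0 and fmax <= 1

    def test_partition_is_exhaustive(self, annulus_field):
        m = annulus_field.mask
        labs = annulus_field.sublayer[m]
        assert (labs > 0).all()
        assert (annulus_field.sublayer[~m] == 0).all()

    def test_sublayer_thresholds(self):
        f = np.array([0.0, 0.33, 1 / 3, 0.5, 0.66, 2 / 3, 1.0])
        labs = sublayer_of_f(f)
        assert list(labs) == [1, 1, 2, 2, 2, 3, 3]

    def test_f_monotone_along_radial_rays(self, annulus, annulus_field):
        _, center = annulus
        for ang in np.linspace(0, 2 * np.pi, 7)[:-1]:
            r = np.linspace(705, 995, 60)
            pts = np.column_stack(
                [center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)]
            )
            fv = annulus_field.f_at(pts)
            fv = fv[~np.isnan(fv)]
            # ray from inner to outer border: f decreases with radius
            # (up to half-cell snapping of the raster lookup)
            assert (np.diff(fv) <= 0.01).all()

    def test_too_coarse_spacing_raises(self):
        region = make_rect_region(length=100, thickness=30)
        with pytest.raises(GeometryError, match="coarse|empty"):
            ws.compute_relative_position_field(region, spacing=5000.0)


class TestThickness:
    def test_concentric_circles(self, annulus):
        region, _ = annulus
        t = ws.estimate_thickness(region, spacing=1.0)
        assert t == pytest.approx(300.0, rel=0.005)

    def test_parallel_segments_with_end_trim(self):
        region = make_rect_region(length=2000, thickness=744)
        t = ws.estimate_thickness(region, spacing=2.0)
        assert t == pytest.approx(744.0, rel=1e-6)

    def test_sinusoidal_outer_vs_brute_force(self):
        # inner y=0, outer y=700+50 sin(2 pi x / 2000), x in [0, 4000]
        x = np.linspace(0, 4000, 2001)
        inner = ws.BorderPolyline(
            np.column_stack([x, np.zeros_like(x)]), role="inner"
        )
        outer = ws.BorderPolyline(
            np.column_stack([x, 700 + 50 * np.sin(2 * np.pi * x / 2000)]),
            role="outer",
        )
        region = ws.build_wall_region(inner, outer, 2.0)
        t = ws.estimate_thickness(region, spacing=2.0)

        # independent brute-force oracle: all-pairs nearest point distances at
        # 0.5 um resolution, pooled both directions, same end trim
        fine_i = ws.resample_polyline(region.inner, 0.5).vertices
        fine_o = ws.resample_polyline(region.outer, 0.5).vertices
        sub_i = ws.resample_polyline(region.inner, 2.0).vertices
        sub_o = ws.resample_polyline(region.outer, 2.0).vertices

        def nearest(a, b):
            out = np.empty(len(a))
            for i in range(0, len(a), 256):
                blk = a[i:i + 256]
                d = np.hypot(
                    blk[:, None, 0] - b[None, :, 0],
                    blk[:, None, 1] - b[None, :, 1],
                )
                out[i:i + 256] = d.min(axis=1)
            return out

        d_i, d_o = nearest(sub_i, fine_o), nearest(sub_o, fine_i)
        t0 = np.median(np.concatenate([d_i, d_o]))
        pooled = []
        for pts, d in ((sub_i, d_i), (sub_o, d_o)):
            arc = np.concatenate(
                [[0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))]
            )
            sel = (arc >= t0) & (arc <= arc[-1] - t0)
            pooled.append(d[sel])
        oracle = np.concatenate(pooled).mean()
        assert t == pytest.approx(oracle, rel=0.002)


class TestSublayerAreas:
    def test_rectangle_equal_thirds(self, rect_field):
        areas = ws.sublayer_areas(rect_field)
        for a in (areas.area_inner, areas.area_middle, areas.area_outer):
            assert a == pytest.approx(1.4 / 3, rel=0.01)
        assert areas.area_total == pytest.approx(1.4, rel=0.005)

    def test_annulus_19_17_15_ratio(self, annulus_field):
        areas = ws.sublayer_areas(annulus_field)
        exp = {
            "outer": np.pi * (1000**2 - 900**2) / 1e6,
            "middle": np.pi * (900**2 - 800**2) / 1e6,
            "inner": np.pi * (800**2 - 700**2) / 1e6,
        }
        assert areas.area_outer == pytest.approx(exp["outer"], rel=0.01)
        assert areas.area_middle == pytest.approx(exp["middle"], rel=0.01)
        assert areas.area_inner == pytest.approx(exp["inner"], rel=0.01)

    def test_partition_conserves_total_area(self, annulus, annulus_field):
        region, _ = annulus
        areas = ws.sublayer_areas(annulus_field)
        assert areas.area_total == pytest.approx(region.area_um2 / 1e6, rel=0.005)

    def test_refinement_convergence(self):
        region = make_rect_region(length=600, thickness=240)
        coarse = ws.sublayer_areas(ws.compute_relative_position_field(region, 4.0))
        fine = ws.sublayer_areas(ws.compute_relative_position_field(region, 2.0))
        for a, b in (
            (coarse.area_inner, fine.area_inner),
            (coarse.area_middle, fine.area_middle),
            (coarse.area_outer, fine.area_outer),
        ):
            assert a == pytest.approx(b, rel=0.005)
        t4 = ws.estimate_thickness(region, spacing=4.0)
        t2 = ws.estimate_thickness(region, spacing=2.0)
        assert t4 == pytest.approx(t2, rel=0.005)
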