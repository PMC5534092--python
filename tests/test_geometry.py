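"""Polygon primitives: areas, centroids, polar resampling, sector windows and
signed swept areas, checked against closed forms and a rasterization oracle."""

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import circle_contour, ellipse_contour
from lvdecomp.errors import (
    DegenerateContourError,
    GridMismatchError,
    InvalidContourError,
    InvalidLandmarkError,
    NotStarShapedError,
)
from lvdecomp.geometry import (
    AngularWindow,
    PlanarContour,
    polar_resample,
    polygon_area,
    polygon_centroid,
    septal_window,
    swept_sector_area,
)
from oracles import raster_swept_area, regular_ngon_area

SQUARE = PlanarContour(np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]))


def bumpy_contour(r0=30.0, amp=3.0, lobes=4, n=360, center=(0.0, 0.0)):
    """Smooth star-shaped but non-circular test contour."""
    theta = np.arange(n) * (2 * np.pi / n)
    r = r0 + amp * np.cos(lobes * theta)
    return PlanarContour(
        np.stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)], axis=1)
    )


class TestPolygonArea:
    def test_square_closed_form(self):
        assert polygon_area(SQUARE) == pytest.approx(100.0)

    def test_clockwise_input_is_normalized(self):
        cw = PlanarContour(SQUARE.points[::-1].copy())
        assert polygon_area(cw) == pytest.approx(100.0)

    def test_regular_ngon_matches_circle(self):
        # 256-gon of radius 35.77 mm: area of a ~40.2 cm^2 circle within 0.05%
        ngon = circle_contour(35.77, n=256)
        assert polygon_area(ngon) == pytest.approx(regular_ngon_area(256, 35.77), rel=1e-12)
        assert polygon_area(ngon) == pytest.approx(np.pi * 35.77**2, rel=5e-4)

    def test_matches_shapely_on_irregular_contour(self):
        c = bumpy_contour()
        assert polygon_area(c) == pytest.approx(shapely.Polygon(c.points).area, rel=1e-12)

    def test_scaling_scales_area_quadratically(self):
        c = bumpy_contour()
        assert polygon_area(c.scaled(2.5)) == pytest.approx(2.5**2 * polygon_area(c))

    @pytest.mark.parametrize(
        "points",
        [
            [[0, 0], [1, 1]],
            [[0, 0], [1, 1], [1, 1], [0, 0]],  # duplicates collapse below 3
        ],
    )
    def test_too_few_points_rejected(self, points):
        with pytest.raises(InvalidContourError):
            PlanarContour(np.asarray(points, dtype=float))

    def test_collinear_contour_rejected_at_centroid(self):
        line = PlanarContour(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        with pytest.raises(DegenerateContourError):
            polygon_centroid(line)


class TestCentroid:
    def test_square(self):
        assert polygon_centroid(SQUARE) == pytest.approx((5.0, 5.0))

    def test_offset_circle(self):
        c = circle_contour(20.0, center=(12.0, -3.0))
        assert polygon_centroid(c) == pytest.approx((12.0, -3.0), abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        dx=st.floats(-50, 50, allow_nan=False),
        dy=st.floats(-50, 50, allow_nan=False),
    )
    def test_translation_equivariance(self, dx, dy):
        c = bumpy_contour()
        cx, cy = polygon_centroid(c)
        tx, ty = polygon_centroid(c.translated(dx, dy))
        assert tx == pytest.approx(cx + dx, abs=1e-9)
        assert ty == pytest.approx(cy + dy, abs=1e-9)


class TestPolarResample:
    def test_circle_constant_radius(self):
        prof = polar_resample(circle_contour(30.0, n=720), (0, 0), 720)
        assert prof.radii == pytest.approx(np.full(720, 30.0), rel=1e-4)

    def test_offset_center_radii(self):
        prof = polar_resample(circle_contour(30.0, n=1440), (5.0, 0.0), 720)
        assert prof.radii[0] == pytest.approx(25.0, rel=1e-4)
        assert prof.radii[360] == pytest.approx(35.0, rel=1e-4)

    def test_ellipse_polar_formula(self):
        a, b = 30.0, 20.0
        prof = polar_resample(ellipse_contour(a, b, n=2880), (0, 0), 720)
        th = prof.angles
        expected = a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)
        assert prof.radii == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("contour", [circle_contour(30.0), ellipse_contour(30, 20)])
    def test_reconstruction_preserves_area(self, contour):
        prof = polar_resample(contour, polygon_centroid(contour), 720)
        rebuilt = prof.to_polygon()
        assert polygon_area(rebuilt) == pytest.approx(polygon_area(contour), rel=2e-3)

    def test_non_star_shaped_rejected_with_angle(self):
        # crescent: part of the boundary folds back across the same angles
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        r = np.where(np.abs(theta - np.pi) < 0.6, 35 - 60 * (0.6 - np.abs(theta - np.pi)), 30)
        pts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
        with pytest.raises(NotStarShapedError, match="angle"):
            polar_resample(PlanarContour(pts), (0, 0), 720)

    def test_center_outside_rejected(self):
        with pytest.raises(NotStarShapedError):
            polar_resample(circle_contour(5.0, center=(50.0, 0.0)), (0, 0), 360)


class TestSeptalWindow:
    @staticmethod
    def _insertion(angle_deg, r=30.0):
        a = np.deg2rad(angle_deg)
        return (r * np.cos(a), r * np.sin(a))

    def test_construction_facing_rv(self):
        win = septal_window(self._insertion(135), self._insertion(225), (0, 0))
        assert win.label == "septal"
        assert np.rad2deg(win.start) == pytest.approx(135.0)
        assert np.rad2deg(win.end) == pytest.approx(225.0)
        assert np.rad2deg(win.length) == pytest.approx(90.0)
        assert win.contains(np.array([np.pi]))[0]

    def test_partition_of_full_circle(self):
        win = septal_window(self._insertion(135), self._insertion(225), (0, 0))
        assert win.length + win.complement().length == pytest.approx(2 * np.pi)
        assert win.complement().label == "lateral"
        angles = np.arange(720) * (2 * np.pi / 720)
        both = win.contains(angles) ^ win.complement().contains(angles)
        assert both.all()

    @pytest.mark.parametrize("rot", [40.0, 111.0, 250.0, 359.0])
    def test_rotation_equivariance(self, rot):
        base = septal_window(self._insertion(135), self._insertion(225), (0, 0))
        rotated = septal_window(
            self._insertion(135 + rot), self._insertion(225 + rot), (0, 0)
        )
        assert rotated.length == pytest.approx(base.length)
        assert np.mod(rotated.start - base.start, 2 * np.pi) == pytest.approx(
            np.deg2rad(rot) % (2 * np.pi), abs=1e-9
        )

    def test_identical_angle_rejected(self):
        with pytest.raises(InvalidLandmarkError):
            septal_window((10.0, 0.0), (20.0, 0.0), (0.0, 0.0))

    def test_antipodal_insertions_ambiguous(self):
        with pytest.raises(InvalidLandmarkError):
            septal_window((30.0, 0.0), (-30.0, 0.0), (0.0, 0.0))


class TestSweptSectorArea:
    @staticmethod
    def _profiles(r_ed, r_es, center=(0.0, 0.0), n=720):
        ed = polar_resample(circle_contour(r_ed, n=1440, center=center), center, n)
        es = polar_resample(circle_contour(r_es, n=1440, center=center), center, n)
        return ed, es

    def test_annulus_sector_closed_form(self):
        ed, es = self._profiles(30.0, 28.0)
        win = AngularWindow(0.0, 2 * np.pi / 3)
        expected = 0.5 * (900 - 784) * (2 * np.pi / 3)  # ~121.5 mm^2
        assert swept_sector_area(ed, es, win) == pytest.approx(expected, rel=1e-3)

    def test_identity_zero(self):
        ed, es = self._profiles(30.0, 30.0)
        assert swept_sector_area(ed, es, AngularWindow(0, np.pi)) == pytest.approx(0.0, abs=1e-9)

    def test_outward_motion_is_negative(self):
        ed, es = self._profiles(30.0, 32.0)
        win = AngularWindow(0.0, np.pi / 2)
        expected = 0.5 * (900 - 1024) * (np.pi / 2)  # ~-97.4 mm^2
        assert swept_sector_area(ed, es, win) == pytest.approx(expected, rel=1e-3)
        assert swept_sector_area(ed, es, win) < 0

    def test_sector_partition_is_exact(self):
        center = (1.0, -2.0)
        ed = polar_resample(bumpy_contour(30, 3, 4, center=center), center, 720)
        es = polar_resample(bumpy_contour(27, 2, 5, center=center), center, 720)
        win = AngularWindow(np.deg2rad(120), np.deg2rad(240))
        total = swept_sector_area(ed, es, win) + swept_sector_area(ed, es, win.complement())
        dtheta = 2 * np.pi / 720
        full = 0.5 * np.sum(ed.radii**2 - es.radii**2) * dtheta
        assert total == pytest.approx(full, abs=1e-9)

    def test_full_circle_equals_polygon_area_difference(self):
        ced, ces = bumpy_contour(30, 3, 4), bumpy_contour(27, 2, 5)
        ed = polar_resample(ced, (0, 0), 720)
        es = polar_resample(ces, (0, 0), 720)
        win = AngularWindow(0, np.pi)
        full = swept_sector_area(ed, es, win) + swept_sector_area(ed, es, win.complement())
        assert full == pytest.approx(polygon_area(ced) - polygon_area(ces), rel=5e-3)

    def test_rasterization_oracle(self):
        center = (0.0, 0.0)
        ced = bumpy_contour(30, 3, 4)
        ces = bumpy_contour(26, 2, 3)
        ed = polar_resample(ced, center, 720)
        es = polar_resample(ces, center, 720)
        win = AngularWindow(np.deg2rad(120), np.deg2rad(240))
        swept = swept_sector_area(ed, es, win)
        oracle = raster_swept_area(ced, ces, win, center, pixel=0.1)
        assert swept == pytest.approx(oracle, rel=1e-2)

    def test_translation_invariance(self):
        for shift in [(0.0, 0.0), (13.0, -7.0)]:
            center = (1.0 + shift[0], 0.5 + shift[1])
            ed = polar_resample(
                bumpy_contour(30, 3, 4, center=center), center, 720
            )
            es = polar_resample(
                bumpy_contour(27, 2, 5, center=center), center, 720
            )
            val = swept_sector_area(ed, es, AngularWindow(0.3, 2.0))
            if shift == (0.0, 0.0):
                ref = val
        assert val == pytest.approx(ref, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        ed, _ = self._profiles(30.0, 28.0, n=720)
        _, es = self._profiles(30.0, 28.0, n=360)
        with pytest.raises(GridMismatchError):
            swept_sector_area(ed, es, AngularWindow(0, np.pi))
        ed2 = polar_resample(circle_contour(30.0, n=1440), (0, 0), 720)
        es2 = polar_resample(circle_contour(28.0, n=1440, center=(2, 0)), (2, 0), 720)
        with pytest.raises(GridMismatchError):
            swept_sector_area(ed2, es2, AngularWindow(0, np.pi))
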