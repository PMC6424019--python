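"""Geometry engine: loading, hull measures, skeleton graphs, corner sets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamellometry import (
    InvalidSilhouetteError,
    Silhouette,
    detect_corners,
    load_silhouette,
    make_lamella,
    measure_hull,
    random_star_polygon,
    skeletonize_silhouette,
    SyntheticLamellaSpec,
)

from conftest import brute_force_branches, h_mask, ribbon_mask, y_mask


class TestLoading:
    def test_rectangle_mask_area(self, tmp_path):
        """A 40x20 px rectangle at 0.01 mm/px covers 0.4 x 0.2 = 0.08 mm^2."""
        m = np.zeros((100, 100), dtype=np.uint8)
        m[40:60, 30:70] = 255
        import imageio.v3 as iio

        p = tmp_path / "rect.png"
        iio.imwrite(p, m)
        s = load_silhouette(p, scale=0.01)
        assert s.area == pytest.approx(0.08, rel=0.05)

    def test_polygon_csv_unit_square(self, tmp_path):
        p = tmp_path / "sq.csv"
        p.write_text("x_mm,y_mm\n0,0\n1,0\n1,1\n0,1\n")
        s = load_silhouette(p)
        assert s.area == pytest.approx(1.0)
        # orientation normalized to CCW: positive shoelace sum
        x, y = s.polygon[:, 0], s.polygon[:, 1]
        shoelace = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) / 2
        assert shoelace > 0

    def test_raster_polygon_round_trip(self):
        """Synthetic lamella survives raster->polygon->raster at >=99% agreement."""
        sil, _ = make_lamella(SyntheticLamellaSpec(seed=7))
        m1 = sil.mask
        s2 = Silhouette.from_mask(m1, scale=sil.scale)
        m2 = s2.to_mask()
        h = min(m1.shape[0], m2.shape[0])
        w = min(m1.shape[1], m2.shape[1])
        agreement = (m1[:h, :w] == m2[:h, :w]).mean()
        assert agreement >= 0.99

    def test_multi_component_mask_rejected(self):
        m = np.zeros((50, 50), dtype=bool)
        m[5:15, 5:15] = True
        m[30:40, 30:40] = True
        with pytest.raises(InvalidSilhouetteError, match="2 foreground components"):
            Silhouette.from_mask(m, scale=1.0)

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        with pytest.raises(InvalidSilhouetteError):
            Silhouette(polygon=bowtie)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(InvalidSilhouetteError):
            Silhouette(polygon=np.array([[0, 0], [1, 0], [0, 1]], float), scale=0)

    def test_holes_filled_with_warning(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:25, 5:25] = True
        m[12:18, 12:18] = False
        with pytest.warns(UserWarning, match="holes"):
            s = Silhouette.from_mask(m, scale=1.0)
        assert s.holes_filled


class TestHull:
    def test_unit_square_is_its_own_hull(self, unit_square):
        h = measure_hull(unit_square)
        assert h.boundary_silhouette == pytest.approx(4.0)
        assert h.boundary_hull == pytest.approx(4.0)
        assert h.area_silhouette == pytest.approx(1.0)
        assert h.area_hull == pytest.approx(1.0)

    def test_plus_sign_hull(self, plus_sign):
        h = measure_hull(plus_sign)
        assert h.area_silhouette == pytest.approx(5.0)
        assert h.area_hull == pytest.approx(7.0)
        assert h.boundary_silhouette == pytest.approx(12.0)
        assert h.boundary_hull == pytest.approx(4 + 4 * np.sqrt(2))

    def test_hull_gap_grows_with_fold_length(self):
        """Longer folds widen the hull-silhouette gap (deviation driver)."""
        gaps = []
        for ell in (0.4, 0.8, 1.2):
            sil, _ = make_lamella(
                SyntheticLamellaSpec(seed=3, n_folds=10, fold_length=ell)
            )
            h = measure_hull(sil)
            gaps.append(h.area_hull - h.area_silhouette)
        assert gaps[0] < gaps[1] < gaps[2]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        k=st.floats(min_value=0.01, max_value=100),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_scale_equivariance(self, k, seed):
        """Scaling by k multiplies perimeters by k and areas by k^2."""
        rng = np.random.default_rng(seed)
        poly = random_star_polygon(rng)
        s1 = Silhouette(polygon=poly)
        s2 = s1.scaled(k)
        h1, h2 = measure_hull(s1), measure_hull(s2)
        assert h2.boundary_silhouette == pytest.approx(k * h1.boundary_silhouette)
        assert h2.boundary_hull == pytest.approx(k * h1.boundary_hull)
        assert h2.area_silhouette == pytest.approx(k**2 * h1.area_silhouette)
        assert h2.area_hull == pytest.approx(k**2 * h1.area_hull)

    def test_hull_bounds_on_random_polygons(self):
        """P_h <= P_s and A_s <= A_h exactly, over 1000 random star polygons."""
        rng = np.random.default_rng(20240901)
        for _ in range(1000):
            h = measure_hull(Silhouette(polygon=random_star_polygon(rng)))
            assert h.boundary_hull <= h.boundary_silhouette
            assert h.area_silhouette <= h.area_hull


class TestSkeleton:
    def test_straight_ribbon_single_branch(self):
        s = Silhouette.from_mask(ribbon_mask(), scale=0.01)
        g = skeletonize_silhouette(s)
        assert g.n_endpoints == 2
        assert g.n_junctions == 0
        assert g.n_branches == 1

    def test_y_shape_three_branches(self):
        s = Silhouette.from_mask(y_mask(), scale=0.01)
        g = skeletonize_silhouette(s)
        assert g.n_junctions == 1
        assert g.n_endpoints == 3
        assert g.n_branches == 3

    def test_h_shape_five_branches(self):
        s = Silhouette.from_mask(h_mask(), scale=0.01)
        g = skeletonize_silhouette(s)
        assert g.n_junctions == 2
        assert g.n_endpoints == 4
        assert g.n_branches == 5

    @pytest.mark.parametrize("mask_fn", [ribbon_mask, y_mask, h_mask])
    def test_branch_count_matches_brute_force(self, mask_fn):
        """Tracer agrees with neighbour-enumeration on ribbon/Y/H fixtures."""
        s = Silhouette.from_mask(mask_fn(), scale=0.01)
        g = skeletonize_silhouette(s, prune_px=0)
        assert g.n_branches == brute_force_branches(g.skeleton)

    def test_synthetic_branch_count_matches_truth(self):
        sil, truth = make_lamella(SyntheticLamellaSpec(seed=11, n_folds=10))
        g = skeletonize_silhouette(sil)
        assert abs(g.n_branches - truth.expected_branches) <= 1

    def test_empty_mask_rejected(self):
        s = Silhouette(polygon=np.array([[0, 0], [1, 0], [0, 1]], float), scale=1.0)
        s.mask = np.zeros((5, 5), dtype=bool)
        with pytest.raises(InvalidSilhouetteError):
            skeletonize_silhouette(s)


class TestCorners:
    def test_unit_square(self, unit_square):
        cs = detect_corners(unit_square, angle_threshold=30)
        assert cs.n_vertices == 4
        assert cs.n_notches == 0

    def test_plus_sign_vertices_and_notches(self, plus_sign):
        """8 convex 90-degree corners and 4 reflex 270-degree corners."""
        cs = detect_corners(plus_sign)
        assert cs.n_vertices == 12
        assert cs.n_notches == 4
        reflex = [c for c in cs.corners if c.kind == "notch"]
        assert all(c.interior_angle == pytest.approx(270.0) for c in reflex)

    @pytest.mark.parametrize("threshold", [10, 25, 44])
    def test_regular_octagon_no_notches(self, threshold):
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        octagon = Silhouette(polygon=np.column_stack([np.cos(theta), np.sin(theta)]))
        cs = detect_corners(octagon, angle_threshold=threshold)
        assert cs.n_notches == 0

    def test_convex_shapes_have_no_notches(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.normal(size=(30, 2))
            from shapely.geometry import MultiPoint

            hull = np.asarray(MultiPoint(pts).convex_hull.exterior.coords)[:-1]
            cs = detect_corners(Silhouette(polygon=hull))
            assert cs.n_notches == 0

    def test_few_corners_flagged(self):
        tri = Silhouette(polygon=np.array([[0, 0], [1, 0], [0.5, 1]], float))
        with pytest.warns(UserWarning, match="undefined"):
            cs = detect_corners(tri)
        assert cs.too_few

    def test_synthetic_notch_count_matches_truth(self):
        sil, truth = make_lamella(SyntheticLamellaSpec(seed=5, n_folds=10))
        cs = detect_corners(sil)
        assert abs(cs.n_notches - truth.expected_notches) <= 2
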