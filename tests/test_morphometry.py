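"""Descriptor suite: size, shape, Hu moments, branching — oracle-backed."""

import math

import numpy as np
import pytest
from skimage import transform

from vesselmorph import (analytic_contour, aspect, branch_count, contour_geometry,
                         convex_contour, deformity, equivalent_ellipse,
                         feret_diameters, hu_log_moments, measure_vessel,
                         perimeter_ratio, region_from_mask, roundness,
                         shape_factor)
from oracles import (arc_length, hu_moments_bruteforce, hull_vertices_bruteforce,
                     shoelace_area)

MPP = 1.0


def region_of(mask):
    return region_from_mask(mask)


class TestContourGeometry:
    def test_disk_area_matches_pi_r_squared(self, disk_fixture):
        _, _, reg = disk_fixture
        area, _ = contour_geometry(reg, MPP)
        assert area == pytest.approx(math.pi * 50 ** 2, rel=0.02)

    def test_square_area_in_physical_units(self, square_fixture):
        _, _, reg = square_fixture
        area, _ = contour_geometry(reg, 0.25)
        assert area == pytest.approx(625.0)

    def test_square_perimeter_vs_arclength_oracle(self, square_fixture):
        poly, _, reg = square_fixture
        _, perim = contour_geometry(reg, 0.25)
        assert perim == pytest.approx(0.25 * arc_length(poly), rel=0.03)
        assert perim == pytest.approx(100.0, rel=0.03)

    def test_disk_perimeter_vs_circumference(self, disk_fixture):
        _, _, reg = disk_fixture
        _, perim = contour_geometry(reg, MPP)
        assert perim == pytest.approx(2 * math.pi * 50, rel=0.02)


class TestEquivalentEllipse:
    def test_ellipse_axes_recovered(self, ellipse_fixture):
        _, _, reg = ellipse_fixture
        length, width, _ = equivalent_ellipse(reg, MPP)
        assert length == pytest.approx(80, rel=0.02)
        assert width == pytest.approx(40, rel=0.02)

    def test_disk_is_isotropic(self, disk_fixture):
        _, _, reg = disk_fixture
        length, width, _ = equivalent_ellipse(reg, MPP)
        assert length / width <= 1.02

    def test_rotation_invariance(self, ellipse_fixture):
        _, raster45 = analytic_contour("ellipse", semi_major=40, semi_minor=20,
                                       rotation=math.pi / 4)
        l0, w0, _ = equivalent_ellipse(ellipse_fixture[2], MPP)
        l45, w45, _ = equivalent_ellipse(region_of(raster45), MPP)
        assert l45 == pytest.approx(l0, rel=0.02)
        assert w45 == pytest.approx(w0, rel=0.02)

    def test_feret_alternative_on_square(self, square_fixture):
        _, _, reg = square_fixture
        fmax, fmin = feret_diameters(reg, MPP)
        assert fmax == pytest.approx(100 * math.sqrt(2), rel=0.03)
        assert fmin == pytest.approx(100, rel=0.03)


class TestScalarDescriptors:
    def test_aspect_examples(self):
        assert aspect(80, 40) == pytest.approx(2.0)
        assert aspect(14, 7) == pytest.approx(2.0)  # a typical tumour vessel
        with pytest.raises(ValueError):
            aspect(10, 0)

    def test_roundness_closed_forms(self):
        r = 7.3
        assert roundness(2 * math.pi * r, math.pi * r ** 2) == pytest.approx(1.0)
        s = 11.0
        assert roundness(4 * s, s ** 2) == pytest.approx(4 / math.pi)

    def test_rasterized_disk_roundness_band(self, disk_fixture):
        _, _, reg = disk_fixture
        area, perim = contour_geometry(reg, MPP)
        assert 0.98 <= roundness(perim, area) <= 1.06


class TestConvexContour:
    def test_hull_of_convex_shape_is_idempotent(self, disk_fixture):
        _, _, reg = disk_fixture
        hull = convex_contour(reg)
        # every hull vertex lies on the original contour point set
        assert hull.shape[1] == 2
        assert perimeter_ratio(reg) >= 0.97

    def test_star_hull_has_five_tips(self, star_fixture):
        poly, _, reg = star_fixture
        tips = hull_vertices_bruteforce(poly[:-1])
        assert len(tips) == 5  # the 5 outer points, by the brute-force oracle
        hull = convex_contour(reg)
        # pipeline hull vertices all lie near radius 50 (the tips)
        c = poly[:-1].mean(axis=0)
        radii = np.hypot(*(hull - c).T)
        assert radii.max() <= 51.5

    def test_hull_area_dominates_region_area(self, star_fixture):
        _, _, reg = star_fixture
        hull = convex_contour(reg)
        hull_area = shoelace_area(np.vstack([hull, hull[:1]]))
        assert hull_area >= reg.area_px


class TestPerimeterRatioAndDeformity:
    def test_convex_shape_ratio_is_one(self, disk_fixture):
        assert perimeter_ratio(disk_fixture[2]) == pytest.approx(1.0, abs=0.03)

    def test_star_ratio_matches_polygon_oracle(self, star_fixture):
        # exact oracle on the generating polygons: pentagon-of-tips
        # perimeter over star perimeter (~0.82 for R=50, r=20)
        poly, _, reg = star_fixture
        tips = poly[:-1][[0, 2, 4, 6, 8]]
        hull_perim = arc_length(np.vstack([tips, tips[:1]]))
        oracle = hull_perim / arc_length(poly)
        measured = perimeter_ratio(reg)
        assert measured < 0.85
        assert measured == pytest.approx(oracle, rel=0.05)

    def test_ratio_never_exceeds_one(self, disk_fixture, square_fixture,
                                     ellipse_fixture, star_fixture):
        for _, _, reg in (disk_fixture, square_fixture, ellipse_fixture, star_fixture):
            assert perimeter_ratio(reg) <= 1.01

    def test_disk_deformity_below_one_percent(self, disk_fixture):
        _, _, reg = disk_fixture
        assert deformity(reg, MPP) <= 0.01 * reg.area_px

    def test_star_deformity_matches_shoelace_oracle(self, big_star_fixture):
        poly, _, reg = big_star_fixture
        tips = poly[:-1][[0, 2, 4, 6, 8]]
        oracle = shoelace_area(np.vstack([tips, tips[:1]])) - shoelace_area(poly)
        assert deformity(reg, MPP) == pytest.approx(oracle, rel=0.05)

    def test_deformity_never_negative_beyond_epsilon(self, square_fixture,
                                                     ellipse_fixture):
        for _, _, reg in (square_fixture, ellipse_fixture):
            assert deformity(reg, MPP) >= -2.0  # px^2-scale rasterization slack


class TestHuMoments:
    def test_disk_h1_analytic(self, disk_fixture):
        _, raster, _ = disk_fixture
        sig = hu_log_moments(raster)
        assert sig.h[0] == pytest.approx(1 / (2 * math.pi), rel=0.01)

    def test_matches_bruteforce_oracle_on_random_polygons(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(5, 12)
            angles = np.sort(rng.uniform(0, 2 * math.pi, n))
            radii = rng.uniform(10, 40, n)
            poly = np.column_stack([50 + radii * np.sin(angles),
                                    50 + radii * np.cos(angles)])
            from skimage.draw import polygon2mask
            mask = polygon2mask((100, 100), poly)
            if mask.sum() < 20:
                continue
            sig = hu_log_moments(mask)
            oracle = hu_moments_bruteforce(mask)
            np.testing.assert_allclose(sig.h, oracle, rtol=1e-6, atol=1e-300)

    def test_translation_and_rotation_invariance(self):
        # asymmetric blob: all seven invariants are well-conditioned
        # (symmetric shapes have h2, h3 ~ 0, pure rasterization noise)
        from skimage.draw import polygon2mask
        rng = np.random.default_rng(3)
        angles = np.sort(rng.uniform(0, 2 * math.pi, 9))
        radii = rng.uniform(15, 45, 9)
        poly = np.column_stack([60 + radii * np.sin(angles),
                                60 + radii * np.cos(angles)])
        mask = polygon2mask((200, 200), poly + 30)
        a = hu_log_moments(mask)
        b = hu_log_moments(transform.rotate(mask.astype(float), 37.0, order=0) > 0.5)
        assert a.defined.all() and b.defined.all()
        np.testing.assert_allclose(a.m, b.m, atol=1e-2)
        # quarter-turn and translation are exact for pixel rasters
        c = hu_log_moments(np.rot90(mask))
        np.testing.assert_allclose(a.m, c.m, atol=1e-9)

    def test_mirror_flips_h7_only(self, star_fixture):
        rng = np.random.default_rng(0)
        poly = np.column_stack([50 + rng.uniform(10, 40, 7) * np.sin(np.sort(rng.uniform(0, 2 * math.pi, 7))),
                                50 + rng.uniform(10, 40, 7)])
        from skimage.draw import polygon2mask
        mask = polygon2mask((110, 110), poly)
        a = hu_log_moments(mask)
        b = hu_log_moments(mask[:, ::-1])
        np.testing.assert_allclose(a.h[:6], b.h[:6], rtol=1e-9)
        assert b.h[6] == pytest.approx(-a.h[6], rel=1e-9)


class TestShapeFactor:
    def test_identical_shape_and_hull_gives_zero(self, disk_fixture):
        _, _, reg = disk_fixture
        assert shape_factor(reg) <= 0.05

    def test_star_exceeds_disk(self, disk_fixture, star_fixture):
        assert shape_factor(star_fixture[2]) > shape_factor(disk_fixture[2])

    def test_index_restriction(self, star_fixture):
        full = shape_factor(star_fixture[2], indices=(1, 2, 3, 4, 5, 6, 7))
        restricted = shape_factor(star_fixture[2], indices=(1, 2))
        assert restricted <= full


class TestBranchCount:
    def test_straight_bar_has_no_branches(self):
        bar = np.zeros((40, 220), bool)
        bar[15:25, 10:210] = True
        assert branch_count(region_of(bar)) == 0

    @pytest.mark.parametrize("arms", [3, 4])
    def test_junctions_count_one_node(self, arms):
        size = 300
        img = np.zeros((size, size), bool)
        yy, xx = np.mgrid[:size, :size]
        c = size // 2
        for k in range(arms):
            a = 2 * math.pi * k / arms + (0.5 if arms == 3 else 0)
            du, dv = math.cos(a), math.sin(a)
            t = np.clip((yy - c) * du + (xx - c) * dv, 0, 100)
            img |= ((yy - c) - t * du) ** 2 + ((xx - c) - t * dv) ** 2 <= 25
        reg = region_of(img)
        assert branch_count(reg) == 1
        # oracle: skeleton pixels with >= 3 neighbours exist and cluster once
        from skimage.morphology import skeletonize
        from scipy import ndimage as ndi
        skel = skeletonize(reg.filled_image)
        k = np.ones((3, 3), int); k[1, 1] = 0
        nodes = skel & (ndi.convolve(skel.astype(int), k, mode="constant") >= 3)
        _, n = ndi.label(nodes, structure=np.ones((3, 3), int))
        assert n == 1


class TestMeasureVessel:
    def test_disk_record_is_regular(self):
        _, raster = analytic_contour("disk", radius=25)
        m = measure_vessel(region_of(raster), MPP)
        assert m.aspect == pytest.approx(1.0, abs=0.02)
        assert m.roundness == pytest.approx(1.0, abs=0.06)
        assert m.perimeter_ratio == pytest.approx(1.0, abs=0.03)
        assert m.deformity <= 0.01 * m.area
        assert m.shape_factor <= 0.05
        assert m.branch_count == 0

    def test_ellipse_aspect_two(self, ellipse_fixture):
        m = measure_vessel(ellipse_fixture[2], MPP)
        assert m.aspect == pytest.approx(2.0, abs=0.04)

    def test_star_is_most_irregular(self, disk_fixture, ellipse_fixture, star_fixture):
        md = measure_vessel(disk_fixture[2], MPP)
        me = measure_vessel(ellipse_fixture[2], MPP)
        ms = measure_vessel(star_fixture[2], MPP)
        assert md.roundness <= me.roundness <= ms.roundness
        # convex shapes have deformity ~0 up to rasterization noise
        # (< 1% of area), so ordering holds with that slack
        assert md.deformity <= me.deformity + 0.01 * md.area
        assert me.deformity <= ms.deformity
        assert md.perimeter_ratio >= me.perimeter_ratio - 0.01 >= ms.perimeter_ratio - 0.01

    def test_scale_behavior_is_exact(self, star_fixture):
        reg = star_fixture[2]
        m1 = measure_vessel(reg, 1.0)
        m2 = measure_vessel(reg, 2.0)
        assert m2.length == pytest.approx(2 * m1.length)
        assert m2.width == pytest.approx(2 * m1.width)
        assert m2.perimeter == pytest.approx(2 * m1.perimeter)
        assert m2.area == pytest.approx(4 * m1.area)
        assert m2.deformity == pytest.approx(4 * m1.deformity)
        for f in ("aspect", "roundness", "perimeter_ratio", "shape_factor"):
            assert getattr(m2, f) == getattr(m1, f)
        assert m2.branch_count == m1.branch_count

    def test_rotation_invariance_all_descriptors(self, ellipse_fixture):
        _, rot = analytic_contour("ellipse", semi_major=40, semi_minor=20,
                                  rotation=math.pi / 3)
        m0 = measure_vessel(ellipse_fixture[2], MPP)
        m1 = measure_vessel(region_of(rot), MPP)
        for f in ("area", "length", "width", "perimeter", "aspect", "roundness",
                  "perimeter_ratio"):
            assert getattr(m1, f) == pytest.approx(getattr(m0, f), rel=0.02), f
        assert abs(m1.deformity - m0.deformity) <= 0.02 * m0.area
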