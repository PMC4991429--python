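import numpy as np
import pytest

from vesselmorph import analytic_contour, region_from_mask


@pytest.fixture(scope="session")
def disk_fixture():
    poly, raster = analytic_contour("disk", radius=50)
    return poly, raster, region_from_mask(raster)


@pytest.fixture(scope="session")
def square_fixture():
    poly, raster = analytic_contour("square", side=100)
    return poly, raster, region_from_mask(raster)


@pytest.fixture(scope="session")
def ellipse_fixture():
    poly, raster = analytic_contour("ellipse", semi_major=40, semi_minor=20)
    return poly, raster, region_from_mask(raster)


@pytest.fixture(scope="session")
def star_fixture():
    poly, raster = analytic_contour("star", outer=50, inner=20, n_points=5)
    return poly, raster, region_from_mask(raster)


@pytest.fixture(scope="session")
def big_star_fixture():
    poly, raster = analytic_contour("star", outer=80, inner=32, n_points=5)
    return poly, raster, region_from_mask(raster)


def make_ring(outer_r=23, inner_r=20, gap_px=0, size=None):
    """Annulus raster, optionally with an arc gap of ~gap_px width."""
    size = size or 2 * outer_r + 10
    c = size / 2
    yy, xx = np.mgrid[:size, :size]
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    ring = (d2 <= outer_r ** 2) & (d2 > inner_r ** 2)
    if gap_px > 0:
        half_angle = gap_px / (2.0 * outer_r)
        ang = np.arctan2(yy - c, xx - c)
        ring &= ~(np.abs(ang) <= half_angle)
    return ring
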