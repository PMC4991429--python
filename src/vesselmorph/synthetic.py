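"""Synthetic IHC phantoms with per-vessel ground truth.

Renders calibrated tiles that emulate CD31/DAB histology: a
hematoxylin-tinted tissue background (optionally with a white
no-tissue margin), vessel walls painted in DAB brown at a fixed
optical density, and i.i.d. Gaussian pixel noise. Shape families cover
the morphologies seen in microvascular segments: closed and open
endothelial rings, elongated tubes, branched (Y) tubes, and star-shaped
cisterns. Every family is calibrated so that the equivalent-ellipse
minor axis of the rasterized filled shape equals the requested
``caliber_um`` — the same caliber the classifier measures — and the
ground truth records the exact rasterized areas and axes.

Also provides ``analytic_contour``: exact generating polygons together
with their rasterizations, for shoelace / arc-length descriptor
oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from skimage import draw, measure, morphology

from .classify import SegmentClass, classify_width
from .config import SegmentThresholds, StainConfig
from .segmentation import ImageTile

SHAPES = ("ring", "open_ring", "ellipse_ring", "tube", "branched_tube", "star_cistern")


@dataclass
class SyntheticVesselSpec:
    """One vessel to paint: family, placement and target caliber."""

    shape: str
    center_um: tuple                 # (row, col) in um
    caliber_um: float                # target equivalent-ellipse minor axis
    length_um: Optional[float] = None
    wall_thickness_um: float = 3.0
    gap_fraction: float = 0.0        # open_ring only; fraction of the circumference
    rotation: float = 0.0            # radians
    true_class: Optional[SegmentClass] = None

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.caliber_um <= 0:
            raise ValueError("caliber_um must be positive")
        if not (0.0 <= self.gap_fraction < 0.5):
            raise ValueError("gap_fraction must be in [0, 0.5)")
        if self.length_um is None:
            self.length_um = self.caliber_um * {
                "ring": 1.0, "open_ring": 1.0, "ellipse_ring": 2.0,
                "tube": 4.0, "branched_tube": 3.0, "star_cistern": 2.5}[self.shape]


@dataclass
class GroundTruthVessel:
    index: int
    true_class: SegmentClass
    centroid_um: tuple
    area_px: int
    area_um2: float
    major_um: float
    minor_um: float
    stained_px: int
    branch_count: Optional[int]  # None: no defined expectation (star cisterns)


@dataclass
class PhantomGroundTruth:
    specs: list
    tissue_px: int
    tissue_fraction: float
    stained_pixel_count: int
    vessels: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# shape geometry, calibrated to the target caliber


def _capsule_width_for_minor(caliber: float, length: float) -> float:
    """Drawn width of a capsule whose equivalent-ellipse minor axis is
    ``caliber``. A rectangle of width w has minor axis w*2/sqrt(3), so
    the drawn width is solved from the exact capsule second moments."""

    def minor_of(w):
        a = max(length - w, 0.0)
        mu00 = a * w + math.pi * w * w / 4.0
        mu02 = a * w ** 3 / 12.0 + math.pi * w ** 4 / 64.0
        return 4.0 * math.sqrt(mu02 / mu00) - caliber

    lo, hi = 0.2 * caliber, 1.05 * caliber
    if minor_of(hi) < 0:       # shape shorter than wide: plain disk
        return caliber
    return brentq(minor_of, lo, hi, xtol=1e-6)


def _minor_axis_of_mask(mask: np.ndarray, mpp: float) -> float:
    rp = measure.regionprops(mask.astype(np.uint8))[0]
    return rp.axis_minor_length * mpp


def _fill_local(kind: str, geom: dict, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Filled shape on a um grid centred at the vessel centre."""
    th = geom["rotation"]
    ca, sa = math.cos(th), math.sin(th)
    u = yy * ca + xx * sa      # along major axis
    v = -yy * sa + xx * ca
    if kind in ("ring", "open_ring", "ellipse_ring"):
        a, b = geom["semi_major"], geom["semi_minor"]
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if kind == "tube":
        half, r = geom["segment_half"], geom["radius"]
        t = np.clip(u, -half, half)
        return (u - t) ** 2 + v ** 2 <= r * r
    if kind == "branched_tube":
        arm, r = geom["arm"], geom["radius"]
        out = np.zeros(yy.shape, dtype=bool)
        for k in range(3):
            ang = th + k * 2.0 * math.pi / 3.0
            du, dv = math.cos(ang), math.sin(ang)
            t = np.clip(yy * du + xx * dv, 0.0, arm)
            out |= (yy - t * du) ** 2 + (xx - t * dv) ** 2 <= r * r
        return out
    raise ValueError(kind)


def _star_polygon_um(geom: dict) -> np.ndarray:
    """Vertices (row, col) um relative to the centre, alternating radii."""
    n, R, r, th = geom["points"], geom["outer"], geom["inner"], geom["rotation"]
    angles = th + np.arange(2 * n) * math.pi / n
    radii = np.where(np.arange(2 * n) % 2 == 0, R, r)
    return np.column_stack([radii * np.sin(angles), radii * np.cos(angles)])


def _rasterize_geom(kind: str, geom: dict, mpp: float, bound_um: float) -> np.ndarray:
    """Rasterize a centred shape on its own local grid (pixel centres at
    (i + 0.5) * mpp from the window origin)."""
    n = int(math.ceil(2.0 * bound_um / mpp)) + 4
    coords = (np.arange(n) + 0.5) * mpp - n * mpp / 2.0
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    if kind == "star_cistern":
        poly_px = _star_polygon_um(geom) / mpp + (n / 2.0 - 0.5)
        return draw.polygon2mask((n, n), poly_px)
    return _fill_local(kind, geom, yy, xx)


def calibrated_geometry(spec: SyntheticVesselSpec) -> tuple:
    """(geometry dict, bounding radius um) with the drawn dimensions
    adjusted so the rasterized minor axis matches ``caliber_um``."""
    kind, cal, length = spec.shape, spec.caliber_um, spec.length_um
    th = spec.rotation
    if kind in ("ring", "open_ring"):
        geom = {"semi_major": cal / 2.0, "semi_minor": cal / 2.0, "rotation": th}
        return geom, cal / 2.0
    if kind == "ellipse_ring":
        a = max(length, cal) / 2.0
        geom = {"semi_major": a, "semi_minor": cal / 2.0, "rotation": th}
        return geom, a
    if kind == "tube":
        w = _capsule_width_for_minor(cal, length)
        geom = {"segment_half": max(length - w, 0.0) / 2.0, "radius": w / 2.0,
                "rotation": th}
        return geom, length / 2.0 + w
    # branched_tube and star_cistern: uniform-scale calibration against a
    # trial rasterization (minor axis scales exactly linearly with the shape)
    calib_mpp = max(cal / 60.0, 0.05)
    if kind == "branched_tube":
        arm = max(length / 2.0, cal * 0.6)
        r = max(cal * 0.18, spec.wall_thickness_um * 1.2)
        trial = {"arm": arm, "radius": r, "rotation": th}
        mask = _rasterize_geom(kind, trial, calib_mpp, arm + 2 * r)
        s = cal / _minor_axis_of_mask(mask, calib_mpp)
        geom = {"arm": arm * s, "radius": r * s, "rotation": th}
        return geom, geom["arm"] + 2 * geom["radius"]
    if kind == "star_cistern":
        R = max(length, cal) / 2.0
        trial = {"points": 7, "outer": R, "inner": 0.55 * R, "rotation": th}
        mask = _rasterize_geom(kind, trial, calib_mpp, R * 1.2)
        s = cal / _minor_axis_of_mask(mask, calib_mpp)
        geom = {"points": 7, "outer": R * s, "inner": 0.55 * R * s, "rotation": th}
        return geom, geom["outer"] * 1.1
    raise ValueError(kind)


def rasterize_spec(spec: SyntheticVesselSpec, mpp: float, tile_shape: tuple) -> tuple:
    """((row0, col0), filled, wall) local boolean masks for one vessel.

    The wall is the filled shape minus its erosion by the wall
    thickness; for ``open_ring`` a wedge of ``gap_fraction`` of the
    circumference is cut out of the wall, emulating a broken
    endothelial outline.
    """
    geom, bound = calibrated_geometry(spec)
    cr, cc = spec.center_um
    half_px = int(math.ceil((bound + spec.wall_thickness_um + 2) / mpp)) + 2
    r0 = int(round(cr / mpp)) - half_px
    c0 = int(round(cc / mpp)) - half_px
    n = 2 * half_px
    rows = (np.arange(r0, r0 + n) + 0.5) * mpp - cr
    cols = (np.arange(c0, c0 + n) + 0.5) * mpp - cc
    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    if spec.shape == "star_cistern":
        poly_px = (_star_polygon_um(geom) + (cr, cc)) / mpp - 0.5
        poly_local = poly_px - (r0, c0)
        filled = draw.polygon2mask((n, n), poly_local)
    else:
        filled = _fill_local(spec.shape, geom, yy, xx)
    if r0 < 0 or c0 < 0 or r0 + n > tile_shape[0] or c0 + n > tile_shape[1]:
        raise ValueError(f"vessel at {spec.center_um} um does not fit in the tile")

    wall_px = max(1, int(round(spec.wall_thickness_um / mpp)))
    wall = filled & ~morphology.erosion(filled, morphology.disk(wall_px))
    if spec.shape == "open_ring" and spec.gap_fraction > 0:
        ang = np.arctan2(yy, xx)
        half_gap = spec.gap_fraction * math.pi
        delta = np.angle(np.exp(1j * (ang - spec.rotation)))
        wall &= ~(np.abs(delta) <= half_gap)
    return (r0, c0), filled, wall


# ---------------------------------------------------------------------------
# tile rendering


def od_to_rgb(od_vector, strength: float) -> np.ndarray:
    """Invert OD = -log10((I+1)/256) for a stain at the given density."""
    od = np.asarray(od_vector, dtype=float) * strength
    return 256.0 * 10.0 ** (-od) - 1.0


def render_phantom_tile(specs: list, tile_size_um: float, microns_per_pixel: float,
                        noise_sd: float = 4.0, seed: int = 0, *,
                        min_gap_um: float = 10.0, white_margin_um: float = 0.0,
                        stain: Optional[StainConfig] = None,
                        background_hema_od: float = 0.15,
                        vessel_dab_od: float = 0.9,
                        thresholds: Optional[SegmentThresholds] = None,
                        sample_id: str = "phantom") -> tuple:
    """Paint the specs onto a calibrated tile; returns (ImageTile, truth).

    All randomness (pixel noise only) comes from ``seed``; the same
    specs and seed give a bit-identical tile. Vessels closer than
    ``min_gap_um`` raise an error naming the offending pair.
    """
    stain = stain or StainConfig()
    thresholds = thresholds or SegmentThresholds()
    mpp = microns_per_pixel
    n = int(round(tile_size_um / mpp))
    shape = (n, n)

    margin_px = int(round(white_margin_um / mpp))
    tissue = np.zeros(shape, dtype=bool)
    tissue[margin_px:n - margin_px or None, margin_px:n - margin_px or None] = True

    gap_px = max(1, int(round(min_gap_um / mpp)))
    gap_disk = morphology.disk(gap_px)
    occupied = np.zeros(shape, dtype=np.int32)
    stained = np.zeros(shape, dtype=bool)
    vessels = []
    for i, spec in enumerate(specs):
        (r0, c0), filled, wall = rasterize_spec(spec, mpp, shape)
        nn = filled.shape[0]
        window = (slice(r0, r0 + nn), slice(c0, c0 + nn))
        dilated = morphology.dilation(np.pad(filled, gap_px), gap_disk)
        R0, C0 = r0 - gap_px, c0 - gap_px
        rs, cs = max(R0, 0), max(C0, 0)
        re = min(R0 + nn + 2 * gap_px, n)
        ce = min(C0 + nn + 2 * gap_px, n)
        sub = dilated[rs - R0:re - R0, cs - C0:ce - C0]
        clash = occupied[rs:re, cs:ce][sub]
        if clash.any():
            j = int(clash.max()) - 1
            raise ValueError(f"vessels {j} and {i} are closer than {min_gap_um} um")
        occupied[window][filled] = i + 1
        stained[window] |= wall

        rp = measure.regionprops(filled.astype(np.uint8))[0]
        cy, cx = rp.centroid
        vessels.append(GroundTruthVessel(
            index=i,
            true_class=spec.true_class or classify_width(spec.caliber_um, thresholds),
            centroid_um=((r0 + cy + 0.5) * mpp, (c0 + cx + 0.5) * mpp),
            area_px=int(rp.area),
            area_um2=float(rp.area) * mpp ** 2,
            major_um=rp.axis_major_length * mpp,
            minor_um=rp.axis_minor_length * mpp,
            stained_px=int(wall.sum()),
            branch_count=(1 if spec.shape == "branched_tube"
                          else None if spec.shape == "star_cistern" else 0),
        ))

    stained &= tissue
    rgb = np.empty((n, n, 3), dtype=np.float64)
    rgb[:] = 255.0
    rgb[tissue] = od_to_rgb(stain.hematoxylin_od_vector, background_hema_od)
    rgb[stained] = od_to_rgb(stain.dab_od_vector, vessel_dab_od)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rgb = rgb + rng.normal(0.0, noise_sd, rgb.shape)
    pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    truth = PhantomGroundTruth(
        specs=list(specs), tissue_px=int(tissue.sum()),
        tissue_fraction=float(tissue.mean()),
        stained_pixel_count=int(stained.sum()), vessels=vessels)
    return ImageTile(pixels=pixels, microns_per_pixel=mpp, sample_id=sample_id), truth


# ---------------------------------------------------------------------------
# reference layouts and analytic fixtures


def default_phantom_specs(seed: int = 0, tile_size_um: float = 500.0,
                          min_gap_um: float = 10.0) -> list:
    """A mixed 30-vessel layout on a 0.5 x 0.5 mm tile.

    10 capillaries (8-12 um tubes and closed/open rings), 5
    post-capillaries/metarterioles (16-19 um ellipse rings), 10
    sinusoids (25-45 um: rings, ellipse rings, branched tubes and a
    star cistern) and 5 venules/arterioles (60-90 um rings). Placement
    is rejection-sampled from ``seed`` with a minimum inter-vessel gap.
    """
    rng = np.random.default_rng(seed)
    wanted = []
    for k in range(10):  # capillaries
        cal = float(rng.uniform(8.0, 12.0))
        shape = ("tube", "tube", "tube", "tube", "ring", "ring", "open_ring",
                 "tube", "ring", "tube")[k]
        wanted.append(dict(shape=shape, caliber_um=cal, wall_thickness_um=2.0,
                           rotation=float(rng.uniform(0, math.pi))))
    for k in range(5):   # post-capillaries & metarterioles
        cal = float(rng.uniform(16.0, 19.0))
        wanted.append(dict(shape="ellipse_ring", caliber_um=cal,
                           length_um=cal * 1.8, wall_thickness_um=2.5,
                           rotation=float(rng.uniform(0, math.pi))))
    for k in range(10):  # sinusoids
        cal = float(rng.uniform(25.0, 45.0))
        shape = ("ring", "ellipse_ring", "branched_tube", "ring", "open_ring",
                 "ellipse_ring", "branched_tube", "star_cistern", "ring",
                 "ellipse_ring")[k]
        wanted.append(dict(shape=shape, caliber_um=cal, wall_thickness_um=3.0,
                           rotation=float(rng.uniform(0, math.pi))))
    for k in range(5):   # venules & arterioles
        cal = float(rng.uniform(60.0, 90.0))
        wanted.append(dict(shape="ring", caliber_um=cal, wall_thickness_um=4.0,
                           rotation=0.0))

    # open rings get a gap small enough for the default 2.5 um closing
    for d in wanted:
        if d["shape"] == "open_ring":
            d["gap_fraction"] = min(0.4, 4.0 / (math.pi * d["caliber_um"]))

    # greedy seeded placement, largest first
    bounds = []
    for d in wanted:
        spec = SyntheticVesselSpec(center_um=(0.0, 0.0), **d)
        _, bound = calibrated_geometry(spec)
        bounds.append(bound + spec.wall_thickness_um)
    order = np.argsort(bounds)[::-1]
    placed = []  # (row, col, bound)
    centers = [None] * len(wanted)
    for idx in order:
        b = bounds[idx]
        lo, hi = b + min_gap_um, tile_size_um - b - min_gap_um
        if lo >= hi:
            raise ValueError("tile too small for the requested vessels")
        for _ in range(20000):
            r, c = rng.uniform(lo, hi, 2)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= (b + pb + min_gap_um) ** 2
                   for pr, pc, pb in placed):
                placed.append((r, c, b))
                centers[idx] = (float(r), float(c))
                break
        else:
            raise ValueError("could not place all vessels; increase the tile size")
    return [SyntheticVesselSpec(center_um=centers[i], **d)
            for i, d in enumerate(wanted)]


def analytic_contour(kind: str, **params) -> tuple:
    """Exact generating polygon plus its rasterization.

    The polygon (closed, (row, col) pixel coordinates) feeds shoelace /
    arc-length oracles; the raster feeds the pipeline descriptors.
    Pixel (i, j) is inside the raster iff its centre satisfies the
    shape inequality.
    """
    if kind == "disk":
        r = params["radius"]
        nv = params.get("n_vertices", 3600)
        size = int(2 * r + 11)
        c = size / 2.0
        t = np.linspace(0, 2 * math.pi, nv + 1)
        poly = np.column_stack([c + r * np.sin(t), c + r * np.cos(t)])
        yy, xx = np.mgrid[:size, :size]
        raster = (yy - c) ** 2 + (xx - c) ** 2 <= r * r
        return poly, raster
    if kind == "square":
        s = int(params["side"])
        size = s + 10
        o = 5
        corners = np.array([[o - .5, o - .5], [o - .5, o + s - .5],
                            [o + s - .5, o + s - .5], [o + s - .5, o - .5],
                            [o - .5, o - .5]])
        raster = np.zeros((size, size), dtype=bool)
        raster[o:o + s, o:o + s] = True
        return corners, raster
    if kind == "ellipse":
        a, b = params["semi_major"], params["semi_minor"]
        rot = params.get("rotation", 0.0)
        nv = params.get("n_vertices", 3600)
        size = int(2 * max(a, b) + 11)
        c = size / 2.0
        t = np.linspace(0, 2 * math.pi, nv + 1)
        y, x = b * np.sin(t), a * np.cos(t)
        yr = y * math.cos(rot) + x * math.sin(rot)
        xr = -y * math.sin(rot) + x * math.cos(rot)
        poly = np.column_stack([c + yr, c + xr])
        yy, xx = np.mgrid[:size, :size]
        dy, dx = yy - c, xx - c
        u = dx * math.cos(rot) + dy * math.sin(rot)
        v = -dx * math.sin(rot) + dy * math.cos(rot)
        raster = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        return poly, raster
    if kind == "star":
        R, r = params["outer"], params["inner"]
        npts = params.get("n_points", 5)
        rot = params.get("rotation", 0.0)
        size = int(2 * R + 11)
        c = size / 2.0
        angles = rot + np.arange(2 * npts) * math.pi / npts
        radii = np.where(np.arange(2 * npts) % 2 == 0, R, r)
        poly = np.column_stack([c + radii * np.sin(angles), c + radii * np.cos(angles)])
        poly = np.vstack([poly, poly[:1]])
        raster = draw.polygon2mask((size, size), poly[:-1])
        return poly, raster
    raise ValueError(f"unknown analytic kind {kind!r}")
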