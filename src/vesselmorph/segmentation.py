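"""Vessel segmentation for CD31/DAB brightfield tiles.

Stages, in order: colour deconvolution of the H-DAB stains into optical
density (OD), tissue detection in HSV space, thresholding of the DAB OD
into a raw stained-pixel mask, morphological closing to seal open
endothelial outlines, and hole filling + labelling into per-vessel
regions. A vessel region is the filled object (wall plus lumen) so that
its width describes the full caliber, while stained-area statistics use
the raw stained mask (endothelial staining only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color, filters, measure, morphology

from .config import ConfigurationError, StainConfig

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ImageTile:
    """A calibrated 8-bit RGB raster, the unit of processing."""

    pixels: np.ndarray            # (H, W, 3) uint8
    microns_per_pixel: float      # um / px
    sample_id: str = "tile"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or self.pixels.size == 0:
            raise ValueError(f"expected non-empty HxWx3 raster, got {self.pixels.shape}")
        if not (self.microns_per_pixel > 0 and np.isfinite(self.microns_per_pixel)):
            raise ValueError("microns_per_pixel must be positive and finite")

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass
class MaskSet:
    """Tissue, raw stained and closed/filled vessel masks for one tile."""

    tissue_mask: np.ndarray
    stained_mask: np.ndarray
    vessel_mask: np.ndarray

    def __post_init__(self):
        if not (self.tissue_mask.shape == self.stained_mask.shape == self.vessel_mask.shape):
            raise ValueError("mask shapes disagree")


@dataclass
class VesselRegion:
    """One labelled, filled vessel object.

    ``filled_image`` is the boolean mask inside ``bbox`` (min_row,
    min_col, max_row, max_col); ``outer_contour`` is the sub-pixel
    boundary traced on the filled mask (closed, global (row, col)
    coordinates); ``hole_contours`` trace the lumina that were filled.
    """

    label: int
    bbox: tuple
    filled_image: np.ndarray
    outer_contour: np.ndarray
    hole_contours: list = field(default_factory=list)
    touches_border: bool = False

    @property
    def area_px(self) -> int:
        return int(self.filled_image.sum())

    def pixel_coords(self) -> tuple:
        """(rows, cols) of filled pixels in global coordinates."""
        rr, cc = np.nonzero(self.filled_image)
        return rr + self.bbox[0], cc + self.bbox[1]


# ---------------------------------------------------------------------------
# operations


def separate_stains(tile: ImageTile, cfg: StainConfig) -> np.ndarray:
    """Per-pixel DAB optical density by colour deconvolution.

    OD = -log10((I + 1) / 256) per channel, projected onto the
    (hematoxylin, DAB, residual) basis; negative projections clamp to 0.
    """
    basis = cfg.od_basis()
    if abs(np.linalg.det(basis)) < 1e-8:
        raise ConfigurationError("degenerate stain basis")
    od = -np.log10((tile.pixels.astype(np.float64) + 1.0) / 256.0)
    conc = od.reshape(-1, 3) @ np.linalg.inv(basis)
    dab = conc[:, 1].reshape(tile.shape)
    return np.maximum(dab, 0.0)


def detect_tissue(tile: ImageTile, cfg: StainConfig) -> np.ndarray:
    """Tissue = saturated or dark pixels in HSV, with small holes filled.

    White (glass / no tissue) has near-zero saturation and high value;
    anything counterstained or pigmented fails one of the two tests.
    Holes smaller than ``tissue_max_hole_um2`` (e.g. vessel lumina,
    adipocyte ghosts) are filled back in.
    """
    hsv = color.rgb2hsv(tile.pixels)
    mask = (hsv[..., 1] >= cfg.tissue_saturation_min) | (hsv[..., 2] <= cfg.tissue_value_max)
    max_hole_px = cfg.tissue_max_hole_um2 / tile.microns_per_pixel ** 2
    holes = ndi.binary_fill_holes(mask) & ~mask  # enclosed background only
    if holes.any():
        labels, n = ndi.label(holes)
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < max_hole_px)
        mask = mask | np.isin(labels, small[small > 0])
    return mask


def threshold_dab(dab_od: np.ndarray, tissue_mask: np.ndarray, cfg: StainConfig) -> np.ndarray:
    """Binary CD31-positive mask; pixels outside tissue are negative."""
    if dab_od.shape != tissue_mask.shape:
        raise ValueError("dab_od and tissue_mask shapes disagree")
    if not tissue_mask.any():
        log.warning("empty tissue mask: no stained pixels possible")
        return np.zeros_like(tissue_mask, dtype=bool)
    inside = dab_od[tissue_mask]
    if cfg.dab_threshold_mode == "fixed":
        thr = cfg.fixed_dab_threshold
    else:
        if float(inside.max() - inside.min()) < 1e-12:
            return np.zeros_like(tissue_mask, dtype=bool)
        thr = filters.threshold_otsu(inside)
    return (dab_od > thr) & tissue_mask


def close_open_outlines(stained_mask: np.ndarray, closing_radius_um: float,
                        microns_per_pixel: float) -> np.ndarray:
    """Morphological closing with a disk, sealing broken endothelial rings.

    Gaps narrower than twice the radius become sealed; a radius that
    rounds to 0 px is the identity. The mask is padded so closing near
    the raster edge behaves as on an infinite background.
    """
    if closing_radius_um < 0:
        raise ValueError("closing radius must be >= 0")
    r = int(round(closing_radius_um / microns_per_pixel))
    if r == 0:
        return stained_mask.copy()
    pad = r + 1
    padded = np.pad(stained_mask, pad)
    closed = morphology.closing(padded, morphology.disk(r))
    return closed[pad:-pad, pad:-pad]


def _trace_contours(mask: np.ndarray, offset: tuple) -> list:
    """Sub-pixel iso-contours (level 0.5) of a padded boolean mask."""
    padded = np.pad(mask, 1).astype(float)
    cs = measure.find_contours(padded, 0.5)
    return [c - 1.0 + np.asarray(offset, dtype=float) for c in cs]


def fill_and_label(closed_mask: np.ndarray, min_area_um2: float,
                   tissue_mask: np.ndarray, microns_per_pixel: float,
                   fill_holes: bool = True) -> list:
    """Fill lumina, label 8-connected components, build VesselRegions.

    Components smaller than ``min_area_um2`` after filling are dropped;
    components with any pixel on the raster edge are flagged
    ``touches_border``. Labels are sequential from 1 in raster order.
    """
    if closed_mask.shape != tissue_mask.shape:
        raise ValueError("mask shapes disagree")
    filled = ndi.binary_fill_holes(closed_mask) if fill_holes else closed_mask.astype(bool)
    labels, _ = ndi.label(filled, structure=np.ones((3, 3), dtype=int))
    min_px = min_area_um2 / microns_per_pixel ** 2
    h, w = closed_mask.shape
    regions = []
    for rp in measure.regionprops(labels):
        if rp.area < min_px:
            continue
        r0, c0, r1, c1 = rp.bbox
        img = rp.image
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        contours = _trace_contours(img, (r0, c0))
        outer = max(contours, key=lambda c: len(c))
        holes_mask = img & ~closed_mask[r0:r1, c0:c1]
        hole_contours = _trace_contours(holes_mask, (r0, c0)) if holes_mask.any() else []
        regions.append(VesselRegion(
            label=len(regions) + 1, bbox=rp.bbox, filled_image=img,
            outer_contour=outer, hole_contours=hole_contours,
            touches_border=touches))
    return regions


def segment_tile(tile: ImageTile, cfg: StainConfig, closing_radius_um: float = 2.5,
                 min_area_um2: float = 12.0, fill_holes: bool = True):
    """Full segmentation: (MaskSet, list of VesselRegion)."""
    dab = separate_stains(tile, cfg)
    tissue = detect_tissue(tile, cfg)
    stained = threshold_dab(dab, tissue, cfg)
    closed = close_open_outlines(stained, closing_radius_um, tile.microns_per_pixel)
    regions = fill_and_label(closed, min_area_um2, tissue, tile.microns_per_pixel,
                             fill_holes=fill_holes)
    vessel = np.zeros_like(closed)
    for reg in regions:
        r0, c0, r1, c1 = reg.bbox
        vessel[r0:r1, c0:c1] |= reg.filled_image
    return MaskSet(tissue_mask=tissue, stained_mask=stained, vessel_mask=vessel), regions


def labels_raster(regions: list, shape: tuple) -> np.ndarray:
    """Paint regions into a uint16 label image (0 = background)."""
    out = np.zeros(shape, dtype=np.uint16)
    for reg in regions:
        r0, c0, r1, c1 = reg.bbox
        view = out[r0:r1, c0:c1]
        view[reg.filled_image] = reg.label
    return out
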