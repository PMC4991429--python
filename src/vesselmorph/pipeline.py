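"""Batch driver: segmentation -> morphometry -> classification.

Processes a directory (or explicit list) of calibrated tiles
independently and deterministically, writing a per-vessel CSV, a
per-sample CSV, mask/label/overlay images and a JSON run manifest with
a checksum for every output file. CSVs are comma-separated UTF-8 with
a fixed column order and `%.6g` floats, so reruns with an identical
configuration are bit-identical.
"""

from __future__ import annotations

import glob as globmod
import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .classify import SegmentClass, classify_vessel, summarize_sample
from .config import RunConfig
from .morphometry import measure_vessel
from .segmentation import ImageTile, labels_raster, segment_tile

log = logging.getLogger(__name__)

VESSEL_COLUMNS = ["sample_id", "label", "segment_class", "area_um2", "length_um",
                  "width_um", "perimeter_um", "aspect", "roundness",
                  "perimeter_ratio", "deformity_um2", "shape_factor",
                  "branch_count", "touches_border"]

OVERLAY_COLORS = {
    SegmentClass.CAPILLARY: (230, 60, 60),
    SegmentClass.POSTCAPILLARY_METARTERIOLE: (240, 160, 40),
    SegmentClass.SINUSOID: (60, 130, 240),
    SegmentClass.VENULE_ARTERIOLE: (60, 190, 90),
    SegmentClass.VEIN_ARTERY: (170, 70, 220),
    None: (128, 128, 128),
}


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO),
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
                        handlers=handlers, force=True)


def load_tile(path, microns_per_pixel: float) -> ImageTile:
    """Read an 8-bit RGB TIFF/PNG tile."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[-1] == 4:
        px = px[..., :3]
    return ImageTile(pixels=px.astype(np.uint8), microns_per_pixel=microns_per_pixel,
                     sample_id=path.stem)


def process_tile(tile: ImageTile, cfg: RunConfig):
    """Run one tile through all stages.

    Returns (masks, list of (region, morphometry, segment), summary).
    The summary is None when the tile holds no tissue (flagged, not
    fatal).
    """
    masks, regions = segment_tile(tile, cfg.stain, cfg.closing_radius_um,
                                  cfg.min_area_um2, fill_holes=cfg.include_lumen)
    triples = []
    for region in regions:
        morph = measure_vessel(region, tile.microns_per_pixel,
                               smooth_window=cfg.contour_smooth_window,
                               width_metric=cfg.width_metric,
                               shape_factor_indices=cfg.shape_factor_indices)
        seg = classify_vessel(morph, cfg.thresholds)
        triples.append((region, morph, seg))
    if not masks.tissue_mask.any():
        log.warning("sample %s: no tissue detected", tile.sample_id)
        return masks, triples, None
    summary = summarize_sample(triples, masks, tile.microns_per_pixel,
                               sample_id=tile.sample_id,
                               exclude_border_from_shape_stats=cfg.exclude_border_from_shape_stats)
    return masks, triples, summary


def vessel_rows(tile: ImageTile, triples) -> list:
    rows = []
    for region, m, seg in triples:
        rows.append({"sample_id": tile.sample_id, "label": region.label,
                     "segment_class": seg.value if seg else "excluded",
                     "area_um2": m.area, "length_um": m.length, "width_um": m.width,
                     "perimeter_um": m.perimeter, "aspect": m.aspect,
                     "roundness": m.roundness, "perimeter_ratio": m.perimeter_ratio,
                     "deformity_um2": m.deformity, "shape_factor": m.shape_factor,
                     "branch_count": m.branch_count,
                     "touches_border": region.touches_border})
    return rows


def render_overlay(tile: ImageTile, regions, classes) -> tuple:
    """(binary uint8 vessel view, RGB overlay coloured by segment).

    The binary view shows the detected vessels in white on black; the
    overlay tints each vessel's pixels by its segment colour on top of
    the original tile.
    """
    binary = np.zeros(tile.shape, dtype=np.uint8)
    overlay = tile.pixels.copy()
    for region, seg in zip(regions, classes):
        rr, cc = region.pixel_coords()
        binary[rr, cc] = 255
        color = np.array(OVERLAY_COLORS.get(seg, OVERLAY_COLORS[None]), dtype=np.uint8)
        overlay[rr, cc] = (0.5 * overlay[rr, cc] + 0.5 * color).astype(np.uint8)
    return binary, overlay


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _resolve_inputs(cfg: RunConfig) -> list:
    paths = []
    for item in cfg.inputs:
        p = Path(item)
        if p.is_dir():
            paths += sorted(q for q in p.iterdir()
                            if q.suffix.lower() in (".png", ".tif", ".tiff"))
        elif any(ch in str(item) for ch in "*?["):
            paths += sorted(Path(q) for q in globmod.glob(str(item)))
        else:
            paths.append(p)
    return paths


def run_batch(cfg: RunConfig, write_images: bool = True):
    """Process every input tile and write all tabular/graphical outputs.

    Returns (vessel DataFrame, sample DataFrame, manifest dict). A tile
    that fails to load is logged and skipped; no readable inputs is an
    error.
    """
    paths = _resolve_inputs(cfg)
    if not paths:
        raise ValueError("no input images found")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    all_vessels, all_samples, outputs = [], [], []
    counts = {}
    for path in paths:
        try:
            tile = load_tile(path, cfg.microns_per_pixel)
        except Exception as exc:
            log.warning("skipping unreadable tile %s: %s", path, exc)
            continue
        masks, triples, summary = process_tile(tile, cfg)
        all_vessels += vessel_rows(tile, triples)
        if summary is None:
            row = {"sample_id": tile.sample_id, "tissue_area_mm2": 0.0,
                   "total_count": 0, "flag": "no_tissue"}
            all_samples.append(row)
        else:
            row = summary.to_row()
            row["flag"] = ""
            all_samples.append(row)
        counts[tile.sample_id] = len(triples)
        if write_images:
            regions = [t[0] for t in triples]
            classes = [t[2] for t in triples]
            binary, overlay = render_overlay(tile, regions, classes)
            stem = tile.sample_id
            iio.imwrite(out / f"{stem}_vessel_mask.png",
                        (masks.vessel_mask * np.uint8(255)))
            iio.imwrite(out / f"{stem}_stained_mask.png",
                        (masks.stained_mask * np.uint8(255)))
            tifffile.imwrite(out / f"{stem}_labels.tif",
                             labels_raster(regions, tile.shape))
            iio.imwrite(out / f"{stem}_binary.png", binary)
            iio.imwrite(out / f"{stem}_overlay.png", overlay)
            outputs += [out / f"{stem}{suffix}" for suffix in
                        ("_vessel_mask.png", "_stained_mask.png", "_labels.tif",
                         "_binary.png", "_overlay.png")]

    if not counts:
        raise ValueError("no readable input images")

    vessel_df = pd.DataFrame(all_vessels, columns=VESSEL_COLUMNS)
    sample_df = pd.DataFrame(all_samples)
    vessel_csv = out / "vessels.csv"
    sample_csv = out / "samples.csv"
    vessel_df.to_csv(vessel_csv, index=False, float_format="%.6g")
    sample_df.to_csv(sample_csv, index=False, float_format="%.6g")
    outputs += [vessel_csv, sample_csv]

    manifest = {
        "tool": "vesselmorph",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "samples": counts,
        "outputs": {str(p.name): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str,
                                                  sort_keys=True))
    return vessel_df, sample_df, manifest
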