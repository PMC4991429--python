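"""Microvascular segment classification and per-sample summaries.

Each vessel is assigned to one of five segments by its caliber (the
equivalent-ellipse minor axis): capillary, post-capillary/metarteriole,
sinusoid, venule/arteriole, vein/artery. Bands are half-open, the edge
belonging to the larger segment. Sample summaries report the classic
angiogenesis quantifiers — microvessel density (vessels/mm^2 of
tissue), stained-area percentage — plus relative density / relative SA
per segment and per-segment descriptor means.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import SegmentThresholds
from .morphometry import VesselMorphometry
from .segmentation import MaskSet

log = logging.getLogger(__name__)

_MEAN_FIELDS = ("area", "length", "width", "perimeter", "aspect", "roundness",
                "perimeter_ratio", "deformity", "shape_factor", "branch_count")


class SegmentClass(str, enum.Enum):
    CAPILLARY = "capillary"
    POSTCAPILLARY_METARTERIOLE = "postcapillary_metarteriole"
    SINUSOID = "sinusoid"
    VENULE_ARTERIOLE = "venule_arteriole"
    VEIN_ARTERY = "vein_artery"


SEGMENT_ORDER = (SegmentClass.CAPILLARY, SegmentClass.POSTCAPILLARY_METARTERIOLE,
                 SegmentClass.SINUSOID, SegmentClass.VENULE_ARTERIOLE,
                 SegmentClass.VEIN_ARTERY)


def classify_vessel(m: VesselMorphometry, t: SegmentThresholds):
    """Map a vessel to its segment by width; None (logged) below min_width."""
    w = m.width
    if w <= 0:
        raise ValueError("vessel width must be positive")
    if w < t.min_width:
        log.warning("vessel width %.2f um below minimum %.2f um: excluded", w, t.min_width)
        return None
    if w < t.capillary_max_width:
        return SegmentClass.CAPILLARY
    if w < t.postcap_max_width:
        return SegmentClass.POSTCAPILLARY_METARTERIOLE
    if w < t.sinusoid_max_width:
        return SegmentClass.SINUSOID
    if w < t.venule_max_width:
        return SegmentClass.VENULE_ARTERIOLE
    return SegmentClass.VEIN_ARTERY


def classify_width(width_um: float, t: SegmentThresholds):
    """Band lookup for a bare width (ground-truth labelling etc.)."""
    probe = VesselMorphometry(area=1, length=width_um, width=width_um, perimeter=1,
                              aspect=1, roundness=1, perimeter_ratio=1, deformity=0,
                              shape_factor=0, branch_count=0)
    return classify_vessel(probe, t)


@dataclass
class SegmentStats:
    count: int = 0
    density: float = 0.0            # vessels / mm^2
    sa_percent: float = 0.0         # % of tissue pixels
    relative_density: float = math.nan  # % of total count
    relative_sa: float = math.nan       # % of total SA
    descriptor_means: dict = field(default_factory=dict)


@dataclass
class SampleSummary:
    sample_id: str
    tissue_area_mm2: float
    total_count: int
    total_density: float
    total_sa_percent: float
    segments: dict                   # SegmentClass -> SegmentStats
    total_descriptor_means: dict

    def to_row(self) -> dict:
        row = {"sample_id": self.sample_id,
               "tissue_area_mm2": self.tissue_area_mm2,
               "total_count": self.total_count,
               "total_density": self.total_density,
               "total_sa_percent": self.total_sa_percent}
        for f in _MEAN_FIELDS:
            row[f"total_mean_{f}"] = self.total_descriptor_means.get(f, math.nan)
        for seg in SEGMENT_ORDER:
            st = self.segments[seg]
            p = seg.value
            row[f"{p}_count"] = st.count
            row[f"{p}_density"] = st.density
            row[f"{p}_sa_percent"] = st.sa_percent
            row[f"{p}_relative_density"] = st.relative_density
            row[f"{p}_relative_sa"] = st.relative_sa
            for f in _MEAN_FIELDS:
                row[f"{p}_mean_{f}"] = st.descriptor_means.get(f, math.nan)
        return row


def _means(morphs: list) -> dict:
    if not morphs:
        return {f: math.nan for f in _MEAN_FIELDS}
    return {f: float(np.mean([getattr(m, f) for m in morphs])) for f in _MEAN_FIELDS}


def summarize_sample(vessels: list, masks: MaskSet, microns_per_pixel: float,
                     sample_id: str = "sample",
                     exclude_border_from_shape_stats: bool = True) -> SampleSummary:
    """Aggregate (region, morphometry, segment) triples into one summary.

    Density counts every classified vessel (border-touching included);
    descriptor means exclude border-touching vessels, whose geometry is
    truncated by the raster edge. Stained-area percentages use the raw
    stained mask restricted to each segment's filled regions.
    """
    tissue_px = int(masks.tissue_mask.sum())
    if tissue_px == 0:
        raise ValueError("zero tissue area")
    tissue_mm2 = tissue_px * microns_per_pixel ** 2 / 1e6

    per_seg_regions = {seg: [] for seg in SEGMENT_ORDER}
    per_seg_morphs = {seg: [] for seg in SEGMENT_ORDER}
    kept = []
    for region, morph, seg in vessels:
        if seg is None:
            continue
        kept.append((region, morph, seg))
        per_seg_regions[seg].append(region)
        if not (exclude_border_from_shape_stats and region.touches_border):
            per_seg_morphs[seg].append(morph)

    total = len(kept)
    total_sa_px = int((masks.stained_mask & masks.tissue_mask).sum())
    seg_sa_px = {}
    for seg in SEGMENT_ORDER:
        sa = 0
        for region in per_seg_regions[seg]:
            rr, cc = region.pixel_coords()
            sa += int(masks.stained_mask[rr, cc].sum())
        seg_sa_px[seg] = sa
    sa_sum = sum(seg_sa_px.values())

    segments = {}
    for seg in SEGMENT_ORDER:
        n = len(per_seg_regions[seg])
        st = SegmentStats(
            count=n,
            density=n / tissue_mm2,
            sa_percent=100.0 * seg_sa_px[seg] / tissue_px,
            relative_density=(100.0 * n / total) if total else math.nan,
            relative_sa=(100.0 * seg_sa_px[seg] / sa_sum) if sa_sum else math.nan,
            descriptor_means=_means(per_seg_morphs[seg]),
        )
        segments[seg] = st

    all_means_src = []
    for region, morph, seg in kept:
        if not (exclude_border_from_shape_stats and region.touches_border):
            all_means_src.append(morph)

    return SampleSummary(
        sample_id=sample_id,
        tissue_area_mm2=tissue_mm2,
        total_count=total,
        total_density=total / tissue_mm2,
        total_sa_percent=100.0 * total_sa_px / tissue_px,
        segments=segments,
        total_descriptor_means=_means(all_means_src),
    )
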