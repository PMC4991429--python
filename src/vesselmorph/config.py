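"""Run configuration: stain vectors, caliber bands, pipeline knobs.

All physical parameters are in microns; rasters are addressed 0-based
(row, col) and physical area is ``pixel count * microns_per_pixel**2``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised for invalid calibration or threshold settings."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if not np.isfinite(n) or n <= 0:
        raise ConfigurationError(f"stain vector has no magnitude: {v}")
    return v / n


@dataclass
class StainConfig:
    """Optical-density basis and thresholds for H-DAB separation.

    Defaults are the standard Ruifrok–Johnston hematoxylin and DAB
    optical-density vectors; both are renormalised to unit length.
    """

    hematoxylin_od_vector: tuple = (0.650, 0.704, 0.286)
    dab_od_vector: tuple = (0.269, 0.568, 0.778)
    dab_threshold_mode: str = "otsu"  # "otsu" | "fixed"
    fixed_dab_threshold: float = 0.15
    tissue_saturation_min: float = 0.05
    tissue_value_max: float = 0.85
    tissue_max_hole_um2: float = 1000.0

    def __post_init__(self):
        h = _unit(self.hematoxylin_od_vector)
        d = _unit(self.dab_od_vector)
        if np.linalg.norm(np.cross(h, d)) < 1e-6:
            raise ConfigurationError("hematoxylin and DAB stain vectors are collinear")
        if self.dab_threshold_mode not in ("otsu", "fixed"):
            raise ConfigurationError(f"unknown threshold mode {self.dab_threshold_mode!r}")
        self.hematoxylin_od_vector = tuple(h)
        self.dab_od_vector = tuple(d)

    def od_basis(self) -> np.ndarray:
        """3x3 row basis (hematoxylin, DAB, residual) for deconvolution."""
        h = np.asarray(self.hematoxylin_od_vector)
        d = np.asarray(self.dab_od_vector)
        r = np.cross(h, d)
        return np.vstack([h, d, r / np.linalg.norm(r)])


@dataclass
class SegmentThresholds:
    """Caliber bands (equivalent-ellipse minor axis, microns) that map a
    vessel to a microvascular segment.

    Capillaries run to 15 um and sinusoids 20–50 um; the remaining band
    edges interpolate/extrapolate those calibers consistently with
    vascular physiology. Intervals are half-open: a width exactly on an
    edge belongs to the larger segment.
    """

    min_width: float = 3.0
    capillary_max_width: float = 15.0
    postcap_max_width: float = 20.0
    sinusoid_max_width: float = 50.0
    venule_max_width: float = 100.0

    def __post_init__(self):
        edges = (self.min_width, self.capillary_max_width, self.postcap_max_width,
                 self.sinusoid_max_width, self.venule_max_width)
        if not all(a < b for a, b in zip(edges, edges[1:])):
            raise ConfigurationError(f"caliber band edges must increase: {edges}")


@dataclass
class RunConfig:
    """Everything a batch run needs; loadable from YAML."""

    inputs: list = field(default_factory=list)  # paths or globs
    microns_per_pixel: float = 0.25
    stain: StainConfig = field(default_factory=StainConfig)
    thresholds: SegmentThresholds = field(default_factory=SegmentThresholds)
    closing_radius_um: float = 2.5
    min_area_um2: float = 12.0
    include_lumen: bool = True          # fill enclosed lumina before measuring
    exclude_border_from_shape_stats: bool = True
    width_metric: str = "ellipse"       # "ellipse" | "feret"
    shape_factor_indices: tuple = (1, 2, 3, 4, 5, 6, 7)
    contour_smooth_window: int = 3
    output_dir: str = "vesselmorph_out"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        if not (self.microns_per_pixel > 0 and np.isfinite(self.microns_per_pixel)):
            raise ConfigurationError("microns_per_pixel must be positive and finite")
        if self.closing_radius_um < 0 or self.min_area_um2 < 0:
            raise ConfigurationError("closing radius and minimum area must be >= 0")
        if self.width_metric not in ("ellipse", "feret"):
            raise ConfigurationError(f"unknown width metric {self.width_metric!r}")
        if isinstance(self.stain, dict):
            self.stain = StainConfig(**self.stain)
        if isinstance(self.thresholds, dict):
            self.thresholds = SegmentThresholds(**self.thresholds)
        self.shape_factor_indices = tuple(int(i) for i in self.shape_factor_indices)
        if any(i < 1 or i > 7 for i in self.shape_factor_indices):
            raise ConfigurationError("shape_factor_indices must be within 1..7")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
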