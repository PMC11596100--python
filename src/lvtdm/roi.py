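"""Apical region-of-interest construction and the per-frame/per-video pipeline.

The method enhances mid-tones only inside a user-delineated apical region of
interest (in a standard apical echo view the apex is displayed at the top of
the sector) and applies mild Gaussian smoothing outside it.  The two branches
are blended with a feathered mask so no seam is visible at the ROI border:

    out = w * T(frame) + (1 - w) * S(frame)

where ``T`` is the tone curve (with its display rescale, in normalized
units), ``S`` is the smoothing branch, and ``w`` is the per-pixel ROI weight.
All arithmetic is in normalized floating intensities; quantization to 8 bits
happens once, at the very end of the pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.draw import polygon2mask

from .tonemap import ToneMapParams, reinhard_tmo

__all__ = [
    "ROIGeometry",
    "ProcessingConfig",
    "build_roi_mask",
    "apply_lvtdm_frame",
    "apply_lvtdm_video",
    "default_apical_roi",
    "load_config",
    "save_config",
]

_SHAPES = ("polygon", "ellipse", "rectangle")


@dataclass(frozen=True)
class ROIGeometry:
    """Region-of-interest geometry in normalized image coordinates.

    Coordinates are (x, y) with origin at the top-left, x rightward and
    y downward, both in [0, 1].

    shape : 'polygon' | 'ellipse' | 'rectangle'
    coords :
        polygon   — sequence of at least three (x, y) vertices;
        ellipse   — (cx, cy, rx, ry), center and semi-axes;
        rectangle — (x0, y0, x1, y1), opposite corners.
    feather_px : width in pixels of the linear ramp applied inward from the
        region border; 0 gives a hard binary mask.
    """

    shape: str
    coords: tuple
    feather_px: float = 8.0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"ROI shape must be one of {_SHAPES}, got {self.shape!r}")
        if self.feather_px < 0:
            raise ValueError("feather_px must be non-negative")
        coords = self.coords
        if self.shape == "polygon":
            verts = [tuple(map(float, v)) for v in coords]
            if len(verts) < 3:
                raise ValueError("polygon ROI needs at least 3 vertices")
            flat = [c for v in verts for c in v]
            object.__setattr__(self, "coords", tuple(verts))
        else:
            flat = [float(c) for c in coords]
            if len(flat) != 4:
                raise ValueError(f"{self.shape} ROI expects 4 parameters, got {len(flat)}")
            if self.shape == "ellipse" and (flat[2] < 0 or flat[3] < 0):
                raise ValueError("ellipse semi-axes must be non-negative")
            object.__setattr__(self, "coords", tuple(flat))
        vals = [c for c in flat]
        if self.shape == "ellipse":
            vals = flat[:2]  # semi-axes may legitimately exceed the unit square
        if any(c < 0 or c > 1 for c in vals):
            raise ValueError("normalized ROI coordinates must lie in [0, 1]")


def default_apical_roi(feather_px: float = 8.0) -> ROIGeometry:
    """Default ROI: the upper 40% of the image, where the apex is displayed."""
    return ROIGeometry("rectangle", (0.0, 0.0, 1.0, 0.4), feather_px=feather_px)


@dataclass(frozen=True)
class ProcessingConfig:
    """Full configuration of the enhancement pipeline."""

    tonemap: ToneMapParams = field(default_factory=ToneMapParams)
    roi: ROIGeometry = field(default_factory=default_apical_roi)
    outside_smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.outside_smoothing_sigma < 0:
            raise ValueError("outside_smoothing_sigma must be non-negative")


def _binary_membership(geometry: ROIGeometry, height: int, width: int) -> np.ndarray:
    """Rasterize geometry membership at pixel centers."""
    cols = (np.arange(width) + 0.5) / width   # normalized x of pixel centers
    rows = (np.arange(height) + 0.5) / height
    x, y = np.meshgrid(cols, rows)
    if geometry.shape == "rectangle":
        x0, y0, x1, y1 = geometry.coords
        x0, x1 = min(x0, x1), max(x0, x1)
        y0, y1 = min(y0, y1), max(y0, y1)
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    if geometry.shape == "ellipse":
        cx, cy, rx, ry = geometry.coords
        if rx == 0 or ry == 0:
            return np.zeros((height, width), dtype=bool)
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
    # polygon: skimage expects (row, col) vertices in pixel units
    verts = np.array([[vy * height - 0.5, vx * width - 0.5] for vx, vy in geometry.coords])
    return polygon2mask((height, width), verts)


def build_roi_mask(geometry: ROIGeometry, height: int, width: int) -> np.ndarray:
    """Build the per-pixel ROI weight map in [0, 1].

    Weights are 1 strictly inside the geometry beyond the feather band,
    0 strictly outside, and ramp linearly with distance to the border across
    the band.  A degenerate (zero-area) geometry yields an all-zero mask and
    a warning rather than an error, so batch processing can continue.
    """
    if height <= 0 or width <= 0:
        raise ValueError("mask dimensions must be positive")
    inside = _binary_membership(geometry, height, width)
    if not inside.any():
        warnings.warn("ROI geometry has zero rasterized area; mask is all zeros", stacklevel=2)
        return np.zeros((height, width), dtype=float)
    if geometry.feather_px == 0 or inside.all():
        return inside.astype(float)
    # distance (in px) from each inside pixel to the nearest outside pixel
    dist = distance_transform_edt(inside)
    return np.minimum(dist / geometry.feather_px, 1.0)


def apply_lvtdm_frame(
    frame: np.ndarray, mask: np.ndarray, config: ProcessingConfig
) -> np.ndarray:
    """Enhance one normalized frame: tone-map inside the ROI, smooth outside.

    ``frame`` and ``mask`` must share dimensions.  Output stays in [0, 1].
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if frame.shape != mask.shape:
        raise ValueError(f"frame shape {frame.shape} != mask shape {mask.shape}")
    params = config.tonemap
    mapped = reinhard_tmo(frame, params)
    if params.rescale_display:
        mapped = mapped * (1.0 + params.A)
    sigma = config.outside_smoothing_sigma
    smoothed = gaussian_filter(frame, sigma) if sigma > 0 else frame
    out = mask * mapped + (1.0 - mask) * smoothed
    return np.clip(out, 0.0, 1.0)


def apply_lvtdm_video(
    frames: Sequence[np.ndarray] | np.ndarray, config: ProcessingConfig
) -> np.ndarray:
    """Apply the enhancement to every frame of a loop with one shared mask.

    The ROI mask is rasterized once from the first frame's dimensions; a
    dimension change mid-video is rejected naming the offending frame.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) == 0:
        raise ValueError("video has no frames")
    h, w = frames[0].shape
    mask = build_roi_mask(config.roi, h, w)
    out = np.empty((len(frames), h, w), dtype=float)
    for i, f in enumerate(frames):
        if f.shape != (h, w):
            raise ValueError(
                f"frame {i} has shape {f.shape}, expected {(h, w)} (dimension drift)"
            )
        out[i] = apply_lvtdm_frame(f, mask, config)
    return out


# -- configuration files ------------------------------------------------------

def _config_to_dict(config: ProcessingConfig) -> dict:
    return {
        "tonemap": {
            "A": config.tonemap.A,
            "rescale_display": config.tonemap.rescale_display,
        },
        "roi": {
            "shape": config.roi.shape,
            "coords": [list(v) if isinstance(v, (tuple, list)) else v for v in config.roi.coords]
            if config.roi.shape == "polygon"
            else list(config.roi.coords),
            "feather_px": config.roi.feather_px,
        },
        "smoothing": {"sigma_px": config.outside_smoothing_sigma},
    }


def save_config(config: ProcessingConfig, path: str | Path) -> None:
    """Write a pipeline configuration as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = _config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> ProcessingConfig:
    """Read a YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return config_from_dict(data)


def config_from_dict(data: dict) -> ProcessingConfig:
    tm = data.get("tonemap", {})
    params = ToneMapParams(
        A=float(tm.get("A", 1.0)),
        rescale_display=bool(tm.get("rescale_display", True)),
    )
    roi_data = data.get("roi")
    if roi_data is None:
        roi = default_apical_roi()
    else:
        coords = roi_data["coords"]
        shape = roi_data["shape"]
        if shape == "polygon":
            coords = tuple(tuple(v) for v in coords)
        else:
            coords = tuple(coords)
        roi = ROIGeometry(shape, coords, feather_px=float(roi_data.get("feather_px", 8.0)))
    smoothing = data.get("smoothing", {})
    return ProcessingConfig(
        tonemap=params,
        roi=roi,
        outside_smoothing_sigma=float(smoothing.get("sigma_px", 1.0)),
    )
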