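"""Synthetic B-mode echocardiography phantom with speckle and an apical thrombus.

The generator emulates the appearance of an apical-view cine loop well enough
to exercise the enhancement pipeline end to end without clinical data:

* a sector (fan) field of view with black pixels outside it;
* a dark blood-filled ventricular cavity surrounded by a bright elliptical
  myocardial band, apex at the top of the sector (display convention);
* an optional low-contrast thrombus blob at the cavity apex, with its
  ground-truth mask;
* fully developed multiplicative speckle — the squared magnitude of a
  unit-variance circular Gaussian field, i.e. exponential with mean 1 —
  spatially correlated by a small 3x3 point-spread kernel;
* gentle sinusoidal wall motion across frames, so a loop behaves like a
  beating heart rather than a still image.

Intensities are quantized to 8 bits exactly as an exported echo file would
be.  Identical seeds give bit-identical loops.  Ground-truth masks are
defined at the zero-displacement (reference) phase of the motion cycle.
This is a texture phantom, not an acoustic simulation: there is no wave
propagation, beamforming, or depth-dependent resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.ndimage import uniform_filter

from .video_io import CineLoop

__all__ = ["PhantomSpec", "generate_phantom", "measure_cnr"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cine loop.

    Intensity targets are mean reflectivities in [0, 1] and must satisfy
    cavity_mean < thrombus_mean < myocardium_mean — a thrombus is a mid-tone
    structure, brighter than blood but darker than myocardium, which is
    precisely why mid-tone expansion helps see it.  ``speckle_scale`` scales
    the multiplicative noise about its unit mean (1.0 = fully developed
    speckle).  ``motion_amplitude`` is the peak wall displacement as a
    fraction of image height.  Geometry is in normalized (x, y) coordinates
    with the origin at the top-left.
    """

    height: int = 256
    width: int = 256
    n_frames: int = 16
    sector_angle: float = 75.0
    cavity_mean: float = 0.05
    thrombus_mean: float = 0.35
    myocardium_mean: float = 0.75
    background_mean: float = 0.12
    speckle_scale: float = 1.0
    thrombus: tuple[tuple[float, float], tuple[float, float]] | None = (
        (0.5, 0.24),
        (0.07, 0.05),
    )
    motion_amplitude: float = 0.015
    frame_rate: float = 30.0
    seed: int = 0

    # cavity geometry (center and semi-axes, normalized)
    cavity_center: tuple[float, float] = (0.5, 0.45)
    cavity_axes: tuple[float, float] = (0.16, 0.28)
    wall_thickness: float = 0.09

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.n_frames) < 1:
            raise ValueError("height, width and n_frames must be positive")
        if not (0 <= self.cavity_mean < self.thrombus_mean < self.myocardium_mean <= 1):
            raise ValueError(
                "intensity ordering cavity_mean < thrombus_mean < myocardium_mean "
                "within [0, 1] is required"
            )
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be positive")
        if not 0 < self.sector_angle <= 180:
            raise ValueError("sector_angle must be in (0, 180] degrees")
        if self.thrombus is not None:
            (cx, cy), (rx, ry) = self.thrombus
            if not (0 <= cx <= 1 and 0 <= cy <= 1) or rx < 0 or ry < 0:
                raise ValueError("thrombus geometry must lie in the unit square")
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be non-negative")


def _grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    y = (np.arange(spec.height) + 0.5) / spec.height
    x = (np.arange(spec.width) + 0.5) / spec.width
    return np.meshgrid(x, y)


def _ellipse(x, y, cx, cy, rx, ry):
    if rx <= 0 or ry <= 0:
        return np.zeros_like(x, dtype=bool)
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def _sector_mask(spec: PhantomSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fan-shaped field of view: vertex near the top center, opening downward."""
    vx, vy = 0.5, 0.02
    dx, dy = x - vx, y - vy
    angle = np.degrees(np.arctan2(dx, dy))  # 0 = straight down
    radius = np.hypot(dx, dy)
    half = spec.sector_angle / 2.0
    return (np.abs(angle) <= half) & (radius <= 0.95) & (dy >= 0)


def _region_masks(spec: PhantomSpec, displacement: float, x, y) -> dict[str, np.ndarray]:
    """Region membership at a given wall displacement (normalized units)."""
    cx, cy = spec.cavity_center
    rx, ry = spec.cavity_axes
    cavity = _ellipse(x, y, cx, cy, rx + displacement, ry + displacement)
    outer = _ellipse(
        x, y, cx, cy, rx + spec.wall_thickness + displacement, ry + spec.wall_thickness + displacement
    )
    myocardium = outer & ~cavity
    if spec.thrombus is not None:
        (tx, ty), (trx, try_) = spec.thrombus
        thrombus = _ellipse(x, y, tx, ty, trx, try_) & cavity
    else:
        thrombus = np.zeros_like(cavity)
    sector = _sector_mask(spec, x, y)
    return {
        "sector": sector,
        "cavity": cavity & ~thrombus & sector,
        "myocardium": myocardium & sector,
        "thrombus": thrombus & sector,
    }


def generate_phantom(spec: PhantomSpec) -> tuple[CineLoop, dict[str, np.ndarray]]:
    """Generate a seeded cine loop plus ground-truth region masks.

    Each frame is a piecewise-constant reflectivity template multiplied by a
    correlated exponential speckle field, clipped to [0, 1] and quantized to
    8 bits; pixels outside the sector are zero.  The returned masks
    ('sector', 'cavity', 'myocardium', 'thrombus') are boolean arrays at the
    reference (zero-displacement) phase; the cavity mask excludes the
    thrombus.
    """
    rng = np.random.default_rng(spec.seed)
    x, y = _grid(spec)
    truth = _region_masks(spec, 0.0, x, y)
    frames = np.zeros((spec.n_frames, spec.height, spec.width), dtype=np.uint8)
    for t in range(spec.n_frames):
        disp = spec.motion_amplitude * np.sin(2.0 * np.pi * t / spec.n_frames)
        regions = _region_masks(spec, disp, x, y)
        template = np.full((spec.height, spec.width), spec.background_mean)
        template[regions["myocardium"]] = spec.myocardium_mean
        template[regions["cavity"]] = spec.cavity_mean
        template[regions["thrombus"]] = spec.thrombus_mean
        template[~regions["sector"]] = 0.0
        speckle = uniform_filter(rng.exponential(1.0, (spec.height, spec.width)), size=3)
        speckle = 1.0 + spec.speckle_scale * (speckle - 1.0)
        frame = np.clip(template * speckle, 0.0, 1.0)
        frames[t] = np.floor(frame * 255.0 + 0.5).astype(np.uint8)
    loop = CineLoop(frames, frame_rate=spec.frame_rate, source_format="phantom")
    return loop, truth


def measure_cnr(loop, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Contrast-to-noise ratio ``|mean(a) - mean(b)| / std(b)`` over all frames.

    ``loop`` may be a :class:`~lvtdm.video_io.CineLoop` or any (n, h, w) /
    (h, w) array; intensities are used as-is (the ratio is invariant to
    linear rescaling).  Region b is the noise reference — conventionally the
    cavity when quantifying thrombus conspicuity.  A constant region b has
    no noise scale: the CNR is undefined and NaN is returned with a warning.
    """
    frames = loop.frames if isinstance(loop, CineLoop) else np.asarray(loop)
    frames = frames.astype(float)
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both region masks must be non-empty")
    if (mask_a & mask_b).any():
        raise ValueError("region masks must be disjoint")
    a = frames[:, mask_a]
    b = frames[:, mask_b]
    sd = float(b.std())
    if sd == 0.0:
        warnings.warn("noise region is constant; CNR undefined", stacklevel=2)
        return float("nan")
    return float(abs(a.mean() - b.mean()) / sd)
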