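"""Normalized-intensity frames and the parameterized Reinhard tone-mapping operator.

The enhancement at the heart of the method is the global tone curve

    I_out = I_in / (I_in + A),    A > 0

applied to pixel intensities normalized to [0, 1].  ``A`` generalizes the
constant 1 of the classic Reinhard operator: the slope of the curve at the
origin is 1/A, so A < 1 steepens the low/mid-tone response (higher perceived
contrast in dark and mid-gray structures such as a mural thrombus against the
ventricular cavity) while A > 1 flattens it.  The curve maps [0, 1] onto
[0, 1/(1+A)]; for display on standard 8-bit monitors the output is by default
rescaled by (1+A) so the attainable maximum hits full white, preserving the
curve's shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ToneMapParams",
    "normalize_intensity",
    "reinhard_tmo",
    "rescale_for_display",
    "to_luminance",
]


@dataclass(frozen=True)
class ToneMapParams:
    """Parameters of the tone-mapping step.

    Parameters
    ----------
    A : float
        Contrast parameter of the curve ``I/(I+A)``.  Must be positive.
        1.0 reproduces the classic Reinhard operator; values below 1
        increase low/mid-tone contrast.
    rescale_display : bool
        If True (default), multiply the mapped output by ``1+A`` before
        8-bit quantization so the curve's attainable maximum ``1/(1+A)``
        maps to 255.  If False, quantize the raw curve output.
    """

    A: float = 1.0
    rescale_display: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.A) or self.A <= 0:
            raise ValueError(f"contrast parameter A must be positive, got {self.A!r}")


def _validate_unit_interval(frame: np.ndarray, name: str = "frame") -> np.ndarray:
    arr = np.asarray(frame, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D intensity array, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    lo, hi = float(arr.min()), float(arr.max())
    if lo < 0.0 or hi > 1.0:
        raise ValueError(
            f"{name} intensities must lie in [0, 1]; observed range [{lo:g}, {hi:g}]"
        )
    return arr


def normalize_intensity(frame_8bit: np.ndarray) -> np.ndarray:
    """Convert an 8-bit grayscale frame to normalized intensities in [0, 1].

    Values are divided by 255 elementwise.  Input must be integer-valued and
    within [0, 255]; anything else is rejected rather than clipped so that
    out-of-range data is surfaced instead of silently altered.
    """
    arr = np.asarray(frame_8bit)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale frame, got shape {arr.shape}")
    vals = arr.astype(float)
    if not np.all(np.isfinite(vals)) or np.any(vals != np.round(vals)):
        raise ValueError("8-bit frame must contain integer values")
    lo, hi = float(vals.min()), float(vals.max())
    if lo < 0 or hi > 255:
        raise ValueError(
            f"8-bit intensities must lie in [0, 255]; observed range [{lo:g}, {hi:g}]"
        )
    return vals / 255.0


def reinhard_tmo(frame: np.ndarray, params: ToneMapParams | float = ToneMapParams()) -> np.ndarray:
    """Apply the tone curve ``I_out = I_in / (I_in + A)`` elementwise.

    ``params`` may be a :class:`ToneMapParams` or a bare positive ``A``.
    Output lies in ``[0, 1/(1+A)]`` and is strictly increasing in the input.
    """
    if not isinstance(params, ToneMapParams):
        params = ToneMapParams(A=float(params))
    arr = _validate_unit_interval(frame)
    return arr / (arr + params.A)


def rescale_for_display(frame: np.ndarray, params: ToneMapParams) -> np.ndarray:
    """Quantize a tone-mapped frame back to 8 bits for standard monitors.

    With ``rescale_display`` on, the value written is
    ``round(255 * I_out * (1 + A))`` clamped to [0, 255], so the operator's
    attainable maximum maps to full scale; with it off, ``round(255 * I_out)``.
    Rounding is half-away-from-zero, matching common image libraries.
    """
    arr = _validate_unit_interval(frame)
    scale = (1.0 + params.A) if params.rescale_display else 1.0
    scaled = 255.0 * arr * scale
    quantized = np.floor(scaled + 0.5)  # half-away-from-zero for non-negative values
    return np.clip(quantized, 0, 255).astype(np.uint8)


def to_luminance(frame: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) color frame to 8-bit luminance with Rec. 601 weights.

    Echo video is grayscale in substance; color planes occasionally appear in
    exported files and are reduced to Y = 0.299 R + 0.587 G + 0.114 B.
    Grayscale input passes through unchanged.
    """
    arr = np.asarray(frame)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(float)
        y = rgb @ np.array([0.299, 0.587, 0.114])
        return np.clip(np.floor(y + 0.5), 0, 255).astype(np.uint8)
    raise ValueError(f"cannot interpret frame of shape {arr.shape} as grayscale or RGB")
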