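"""Reading and writing echocardiography cine loops.

Supported containers:

* multi-frame DICOM (ultrasound multi-frame SOP class, uncompressed or RLE
  transfer syntaxes) — lossless;
* numbered PNG sequence in a directory — lossless;
* AVI / MP4 through imageio's ffmpeg plugin — lossy, available only when the
  ``imageio-ffmpeg`` backend is installed.

Frames are held internally as an (n_frames, height, width) uint8 array.
MONOCHROME1 DICOMs are inverted to the MONOCHROME2 convention (0 = black) on
read; color frames are reduced to Rec. 601 luminance.  Vendor-proprietary
compressed transfer syntaxes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .tonemap import to_luminance

__all__ = ["CineLoop", "read_cine", "write_cine"]

# Ultrasound Multi-frame Image Storage
_US_MF_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.3.1"

_VIDEO_SUFFIXES = {".avi", ".mp4"}
_DICOM_SUFFIXES = {".dcm", ".dicom"}


@dataclass
class CineLoop:
    """A grayscale cine loop: (n, h, w) uint8 frames plus optional frame rate."""

    frames: np.ndarray
    frame_rate: float | None = None
    source_format: str = "unknown"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim == 2:
            frames = frames[np.newaxis]
        if frames.ndim != 3:
            raise ValueError(f"frames must be (n, h, w), got shape {frames.shape}")
        if frames.shape[0] == 0 or frames.shape[1] == 0 or frames.shape[2] == 0:
            raise ValueError("cine loop has no pixels")
        if frames.dtype != np.uint8:
            vals = frames.astype(float)
            if vals.min() < 0 or vals.max() > 255 or np.any(vals != np.round(vals)):
                raise ValueError("frames must hold 8-bit integers in [0, 255]")
            frames = frames.astype(np.uint8)
        self.frames = frames
        if self.frame_rate is not None and not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


def _grayscale_stack(frames: np.ndarray) -> np.ndarray:
    """Coerce decoder output of shape (n,h,w[,c]) or (h,w[,c]) to (n,h,w) uint8."""
    arr = np.asarray(frames)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        # ambiguous (h, w, c) single frame
        arr = arr[np.newaxis]
    if arr.ndim == 4:
        arr = np.stack([to_luminance(f) for f in arr])
    return arr.astype(np.uint8)


def _read_dicom(path: Path) -> CineLoop:
    ds = pydicom.dcmread(path)
    if "PixelData" not in ds:
        raise ValueError(f"{path}: DICOM file carries no pixel data")
    pixels = ds.pixel_array
    frames = _grayscale_stack(pixels)
    if str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1":
        frames = (255 - frames.astype(np.int16)).astype(np.uint8)
    rate = None
    if getattr(ds, "FrameTime", None):
        ft = float(ds.FrameTime)  # milliseconds per frame
        if ft > 0:
            rate = 1000.0 / ft
    elif getattr(ds, "CineRate", None):
        rate = float(ds.CineRate)
    return CineLoop(frames, frame_rate=rate, source_format="dicom")


def _read_png_sequence(path: Path) -> CineLoop:
    files = sorted(path.glob("*.png")) if path.is_dir() else [path]
    if not files:
        raise ValueError(f"{path}: no PNG frames found")
    frames = [to_luminance(iio.imread(f)) for f in files]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"{path}: PNG frames disagree in dimensions: {sorted(shapes)}")
    return CineLoop(np.stack(frames), source_format="png-sequence")


def _read_video(path: Path) -> CineLoop:
    try:
        raw = iio.imread(path, plugin="FFMPEG")
        meta = iio.immeta(path, plugin="FFMPEG")
    except ImportError as exc:
        raise RuntimeError(
            f"{path}: decoding {path.suffix} requires the imageio ffmpeg backend "
            "(install 'imageio-ffmpeg'); DICOM and PNG sequences need no extra backend"
        ) from exc
    frames = _grayscale_stack(raw)
    rate = meta.get("fps") if isinstance(meta, dict) else None
    return CineLoop(frames, frame_rate=rate, source_format=path.suffix.lstrip("."))


def read_cine(path: str | Path) -> CineLoop:
    """Read a cine loop from DICOM, a PNG sequence (file or directory), or AVI/MP4."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    suffix = path.suffix.lower()
    if path.is_dir() or suffix == ".png":
        return _read_png_sequence(path)
    if suffix in _VIDEO_SUFFIXES:
        return _read_video(path)
    if suffix in _DICOM_SUFFIXES or suffix == "":
        return _read_dicom(path)
    raise ValueError(
        f"{path}: unsupported format {suffix!r} (expected DICOM, PNG sequence, AVI or MP4)"
    )


def _write_dicom(loop: CineLoop, path: Path) -> None:
    # derive the instance UID from the pixel content so identical loops
    # serialize byte-identically (end-to-end determinism on lossless output)
    uid = generate_uid(
        entropy_srcs=[str(loop.frames.shape), loop.frames.tobytes().hex()[:4096]]
    )
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = _US_MF_SOP_CLASS
    file_meta.MediaStorageSOPInstanceUID = uid
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = _US_MF_SOP_CLASS
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.PatientName = ""
    ds.PatientID = ""
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = loop.height
    ds.Columns = loop.width
    ds.NumberOfFrames = loop.n_frames
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    if loop.frame_rate:
        ds.FrameTime = 1000.0 / loop.frame_rate
        ds.CineRate = int(round(loop.frame_rate))
    ds.PixelData = loop.frames.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _write_png_sequence(loop: CineLoop, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(loop.n_frames - 1)))
    for i, frame in enumerate(loop.frames):
        iio.imwrite(path / f"frame_{i:0{width}d}.png", frame)


def _write_video(loop: CineLoop, path: Path) -> None:
    try:
        iio.imwrite(
            path,
            np.repeat(loop.frames[..., np.newaxis], 3, axis=-1),
            plugin="FFMPEG",
            fps=loop.frame_rate or 30,
        )
    except ImportError as exc:
        raise RuntimeError(
            f"{path}: encoding {path.suffix} requires the imageio ffmpeg backend "
            "(install 'imageio-ffmpeg'); use DICOM or a PNG sequence for lossless output"
        ) from exc


def write_cine(loop: CineLoop, path: str | Path, format: str | None = None) -> Path:
    """Write a cine loop; the container is chosen from ``format`` or the suffix.

    DICOM and PNG sequences round-trip pixel data bit-exactly.  AVI/MP4 go
    through a video codec and are documented lossy.
    """
    path = Path(path)
    fmt = (format or "").lower()
    if not fmt:
        suffix = path.suffix.lower()
        if suffix in _DICOM_SUFFIXES:
            fmt = "dicom"
        elif suffix in _VIDEO_SUFFIXES:
            fmt = suffix.lstrip(".")
        elif suffix == "":
            fmt = "png-sequence"
        else:
            raise ValueError(f"cannot infer output format from {path.name!r}")
    if fmt == "dicom":
        _write_dicom(loop, path)
    elif fmt in ("png", "png-sequence"):
        _write_png_sequence(loop, path)
    elif fmt in ("avi", "mp4"):
        _write_video(loop, path)
    else:
        raise ValueError(f"unsupported output format {fmt!r}")
    return path
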