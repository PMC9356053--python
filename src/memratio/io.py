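"""Image containers and file-format plumbing.

Pixel convention used throughout the package: integer pixel-center
coordinates, row-major arrays, origin at the top-left corner. Masks are
boolean arrays of the same shape as the image they refer to; label images
written to disk use 0 for background and the cell id for each cell.
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageMeta:
    """Acquisition metadata for a single-channel 2-D image.

    Defaults describe a down-scaled synthetic frame (512 x 512); the
    acquisition-scale values used for real confocal data (2048 x 2048,
    120 nm pixels, 16-bit) are one configuration change away.
    """

    width: int = 512
    height: int = 512
    pixel_size: float = 120.0  # nm per pixel
    bit_depth: int = 16
    channel_label: str = ""

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("image dimensions must be at least 64 x 64 pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass
class Image2D:
    """A single-channel 2-D image: float pixel grid plus metadata.

    Pixels are kept as float64 internally so that noiseless synthetic
    intensities and region statistics are exact; quantization to the
    declared bit depth happens only on write.
    """

    pixels: np.ndarray
    meta: ImageMeta

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2-D pixel array")
        if self.pixels.shape != self.meta.shape:
            raise ValueError(
                f"pixel array shape {self.pixels.shape} does not match "
                f"metadata shape {self.meta.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TimeLapse:
    """A time-lapse stack: (frames, height, width) array plus frame times."""

    frames: np.ndarray
    times: np.ndarray  # seconds, one per frame
    meta: ImageMeta
    frame_interval: float = 30.0  # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("TimeLapse requires a 3-D (t, y, x) array")
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Image2D:
        return Image2D(self.frames[i], self.meta)


def _dtype_for(bit_depth: int):
    return np.uint8 if bit_depth == 8 else np.uint16


def write_image(path: str | Path, image: Image2D) -> None:
    """Write a single-frame grayscale TIFF, quantized to the declared bit depth."""
    arr = np.clip(np.rint(image.pixels), 0, image.meta.max_value)
    tifffile.imwrite(str(path), arr.astype(_dtype_for(image.meta.bit_depth)))


def read_image(path: str | Path, meta: ImageMeta | None = None) -> Image2D:
    """Read a single-frame grayscale TIFF.

    If ``meta`` is omitted, metadata is inferred from the array (bit depth
    from dtype; the default 120 nm pixel size is assumed).
    """
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame grayscale TIFF, got shape {arr.shape}")
    if meta is None:
        bit_depth = 8 if arr.dtype == np.uint8 else 16
        meta = ImageMeta(width=arr.shape[1], height=arr.shape[0], bit_depth=bit_depth)
    elif arr.shape != meta.shape:
        raise ValueError(f"{path}: image shape {arr.shape} does not match declared {meta.shape}")
    if arr.max(initial=0) > meta.max_value:
        raise ValueError(f"{path}: pixel values exceed declared {meta.bit_depth}-bit depth")
    return Image2D(arr.astype(float), meta)


def write_stack(path: str | Path, stack: TimeLapse) -> None:
    arr = np.clip(np.rint(stack.frames), 0, stack.meta.max_value)
    tifffile.imwrite(str(path), arr.astype(_dtype_for(stack.meta.bit_depth)))


def read_stack(path: str | Path, meta: ImageMeta | None = None,
               frame_interval: float = 30.0) -> TimeLapse:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a multi-frame grayscale TIFF, got shape {arr.shape}")
    if meta is None:
        bit_depth = 8 if arr.dtype == np.uint8 else 16
        meta = ImageMeta(width=arr.shape[2], height=arr.shape[1], bit_depth=bit_depth)
    times = np.arange(arr.shape[0]) * frame_interval
    return TimeLapse(arr.astype(float), times, meta, frame_interval)


def write_label_image(path: str | Path, masks: dict[int, np.ndarray],
                      shape: tuple[int, int]) -> None:
    """Write a label-image TIFF: background 0, each mask painted with its id."""
    label = np.zeros(shape, dtype=np.uint16)
    for cell_id, mask in masks.items():
        label[mask] = cell_id
    tifffile.imwrite(str(path), label)


# --- ImageJ .roi polygon export ------------------------------------------
#
# Minimal writer for the ImageJ ROI binary format (magic "Iout", version
# 226, type 0 = polygon). Only the header fields Fiji needs to display a
# polygon outline are populated. Coordinates are stored as int16 offsets
# from the bounding box, x then y.

_ROI_POLYGON = 0


def write_imagej_roi(path: str | Path, points: np.ndarray, name: str | None = None) -> None:
    """Export a closed polygon boundary as an ImageJ .roi file.

    ``points`` is an (n, 2) array of (row, col) pixel coordinates, as
    produced by ``skimage.measure.find_contours`` on a footprint mask.
    """
    pts = np.asarray(points)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("polygon export needs an (n>=3, 2) coordinate array")
    ys = np.rint(pts[:, 0]).astype(int)
    xs = np.rint(pts[:, 1]).astype(int)
    top, left = int(ys.min()), int(xs.min())
    bottom, right = int(ys.max()), int(xs.max())
    n = len(pts)
    header = struct.pack(
        ">4shBx4hH",
        b"Iout",        # magic
        226,            # version
        _ROI_POLYGON,   # roi type (+ 1 pad byte from "Bx")
        top, left, bottom, right,
        n,
    )
    header += b"\x00" * (64 - len(header))  # remaining header fields unused
    coords = struct.pack(f">{n}h", *(xs - left)) + struct.pack(f">{n}h", *(ys - top))
    Path(path).write_bytes(header + coords)


def write_imagej_roi_zip(path: str | Path, boundaries: dict[int, np.ndarray]) -> None:
    """Export one polygon .roi per cell into a Fiji-readable .zip archive."""
    import io as _io

    with zipfile.ZipFile(str(path), "w", zipfile.ZIP_DEFLATED) as zf:
        for cell_id, pts in boundaries.items():
            buf = _io.BytesIO()
            tmp = Path(str(path) + f".cell{cell_id}.roi.tmp")
            write_imagej_roi(tmp, pts)
            zf.writestr(f"cell_{cell_id:04d}.roi", tmp.read_bytes())
            tmp.unlink()
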