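"""Automated membrane-band and cytoplasm ROI extraction.

Replaces manual tracing of a 5-pixel-wide line ROI just inside the cell
edge with a deterministic construction: the cell footprint is detected on
a Gaussian-blurred copy of the image, and the membrane band is the set
difference between the footprint and its morphological erosion by
``band_width`` pixels — the automated analogue of drawing the line "as
close to the cell interior as possible". A guard ring of ``guard_gap``
pixels separates the band from the cytoplasm region so rim signal does
not bleed into the cytoplasm estimate.

The blurred image is used only for detection; intensity statistics are
always computed downstream on the raw image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import clear_border

from .io import Image2D

__all__ = [
    "SegmentationParams",
    "CellInstance",
    "ROIPair",
    "blur_for_detection",
    "detect_cells",
    "extract_membrane_band",
    "segment_image",
]


@dataclass
class SegmentationParams:
    """Parameters of the membrane/cytoplasm ROI construction.

    ``blur_size`` is the full width of the Gaussian detection blur in
    pixels (sigma = blur_size / 3, the common "size" convention of image
    processing GUIs). ``band_width`` is the membrane band thickness.
    ``detection_threshold`` is either "otsu" or a fixed numeric value
    applied to the blurred image.
    """

    blur_size: float = 5.0  # pixels, full kernel width
    band_width: int = 5  # pixels
    guard_gap: int = 2  # pixels between band and cytoplasm region
    detection_threshold: str | float = "otsu"
    min_cell_area: int = 500  # pixels^2
    max_edge_offset: int = 3  # pixels of inward search for the band anchor

    def __post_init__(self) -> None:
        if self.blur_size < 1:
            raise ValueError("blur_size must be >= 1 pixel")
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1 pixel")
        if self.guard_gap < 0:
            raise ValueError("guard_gap must be >= 0")
        if self.max_edge_offset < 0:
            raise ValueError("max_edge_offset must be >= 0")
        if isinstance(self.detection_threshold, str) and self.detection_threshold != "otsu":
            raise ValueError("detection_threshold must be 'otsu' or a number")

    @property
    def sigma(self) -> float:
        return self.blur_size / 3.0


@dataclass
class CellInstance:
    """One detected cell: id, footprint mask, and outer boundary contour."""

    cell_id: int
    footprint_mask: np.ndarray
    boundary: np.ndarray  # (n, 2) closed contour in (row, col) coordinates


@dataclass
class ROIPair:
    """Membrane band plus cytoplasm mask for one cell; the two never overlap."""

    cell_id: int
    membrane_mask: np.ndarray
    cytoplasm_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.membrane_mask & self.cytoplasm_mask):
            raise ValueError(f"cell {self.cell_id}: membrane and cytoplasm masks overlap")
        if not self.membrane_mask.any() or not self.cytoplasm_mask.any():
            raise ValueError(f"cell {self.cell_id}: empty ROI mask")


def blur_for_detection(image: Image2D, params: SegmentationParams | None = None) -> Image2D:
    """Return a Gaussian-blurred copy used only for cell detection.

    The original image is untouched; nearest-edge padding keeps total
    intensity conserved away from the borders.
    """
    params = params or SegmentationParams()
    px = image.pixels
    if not np.all(np.isfinite(px)) or np.any(px < 0):
        raise ValueError("image must be finite and non-negative")
    blurred = gaussian(px, sigma=params.sigma, mode="nearest", preserve_range=True)
    return Image2D(blurred, image.meta)


def _threshold(blurred: np.ndarray, params: SegmentationParams) -> float:
    if params.detection_threshold == "otsu":
        return float(threshold_otsu(blurred))
    return float(params.detection_threshold)


def detect_cells(blurred: Image2D, params: SegmentationParams | None = None) -> list[CellInstance]:
    """Find cell footprints in a blurred image.

    Thresholds (Otsu by default), fills holes, labels connected
    components, discards objects touching the image border and objects
    smaller than ``min_cell_area``. Touching cells merge into a single
    component — supply instance masks externally when that matters.
    Returns an empty list (with a warning) when nothing is found.
    """
    params = params or SegmentationParams()
    fg = blurred.pixels > _threshold(blurred.pixels, params)
    fg = ndimage.binary_fill_holes(fg)
    fg = clear_border(fg)
    labels, _ = ndimage.label(fg)
    cells: list[CellInstance] = []
    next_id = 1
    for region in measure.regionprops(labels):
        if region.area < params.min_cell_area:
            continue
        mask = labels == region.label
        contours = measure.find_contours(mask.astype(float), 0.5)
        boundary = max(contours, key=len)
        cells.append(CellInstance(cell_id=next_id, footprint_mask=mask, boundary=boundary))
        next_id += 1
    if not cells:
        warnings.warn("no cells detected above threshold", stacklevel=2)
    return cells


def extract_membrane_band(cell: CellInstance,
                          params: SegmentationParams | None = None,
                          intensity: Image2D | None = None) -> ROIPair:
    """Build the membrane band and cytoplasm mask for one detected cell.

    Regions are defined by depth (Euclidean distance from the footprint
    edge): the band spans depths (offset, offset + band_width], the
    cytoplasm everything deeper than offset + band_width + guard_gap,
    with the guard ring between them belonging to neither. When an
    intensity image is supplied, the anchor ``offset`` is chosen in
    0..max_edge_offset to maximize the band's mean intensity — the
    automated analogue of drawing the line ROI on top of the membrane,
    as close to the cell interior as possible, which also compensates
    the slight outward bias of a thresholded boundary. Because the band
    is carved out of the cell's own footprint, it cannot contain pixels
    of a neighboring cell even when footprints touch.
    """
    params = params or SegmentationParams()
    fp = cell.footprint_mask
    depth = ndimage.distance_transform_edt(fp)
    offsets = range(params.max_edge_offset + 1) if intensity is not None else (0,)
    best: tuple[float, np.ndarray] | None = None
    for off in offsets:
        band = (depth > off) & (depth <= off + params.band_width)
        if not band.any():
            continue
        score = float(intensity.pixels[band].mean()) if intensity is not None else 0.0
        if best is None or score > best[0]:
            best = (score, band, off)
    if best is None:
        raise ValueError(f"cell {cell.cell_id}: footprint too small for a "
                         f"{params.band_width}-px band")
    _, band, off = best
    cytoplasm = depth > off + params.band_width + params.guard_gap
    if not cytoplasm.any():
        raise ValueError(
            f"cell {cell.cell_id}: footprint too small for a {params.band_width}-px "
            f"band plus {params.guard_gap}-px gap with a non-empty cytoplasm"
        )
    return ROIPair(cell_id=cell.cell_id, membrane_mask=band, cytoplasm_mask=cytoplasm)


def segment_image(raw: Image2D, params: SegmentationParams | None = None,
                  ) -> list[tuple[CellInstance, ROIPair]]:
    """Convenience pipeline: blur, detect, extract ROIs for every cell.

    Cells whose footprint is too small for the band construction are
    skipped with a warning.
    """
    params = params or SegmentationParams()
    blurred = blur_for_detection(raw, params)
    out = []
    for cell in detect_cells(blurred, params):
        try:
            out.append((cell, extract_membrane_band(cell, params, intensity=raw)))
        except ValueError as exc:
            warnings.warn(str(exc), stacklevel=2)
    return out
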