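"""Per-cell morphology: area in µm², roundness, and the large-cell flag.

Roundness is implemented as circularity, 4πA/P², clamped to at most 1.
Perimeter is the length of the marching-squares contour of the mask after
Douglas-Peucker simplification with a tolerance proportional to the region's
linear size (max(1 px, 0.025·√A)).  A naive pixel-edge perimeter
overestimates boundary length and biases disk circularity down to ~0.92,
while simplification removes raster staircase artifacts without rounding
genuine corners, so disks, squares and ellipses all recover their continuum
values — and the scaled tolerance makes the estimate stable under integer
upsampling of the mask.  Elongated cells score lower, the ordering the
screen relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import find_objects
from skimage.measure import approximate_polygon, find_contours

from .segmentation import CellLabelMap

__all__ = [
    "CellRecord",
    "region_area_um2",
    "region_roundness",
    "mask_roundness",
    "flag_large_cells",
    "extract_cell_records",
    "LARGE_CELL_AREA_UM2",
]

#: screen threshold: cells larger than this are flagged for follow-up
LARGE_CELL_AREA_UM2 = 500.0

#: Douglas-Peucker tolerance: max(floor, coeff * sqrt(region area))
_DP_TOL_FLOOR = 1.0
_DP_TOL_COEFF = 0.025


@dataclass
class CellRecord:
    """One segmented cell's measured features."""

    well: str
    field: int
    label: int
    area_um2: float
    perimeter_um: float
    roundness: float
    ser_spot: float = 0.0
    ser_ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("area must be positive")
        if not (0 < self.roundness <= 1):
            raise ValueError("roundness must lie in (0, 1]")
        if self.ser_spot < 0 or self.ser_ridge < 0:
            raise ValueError("texture responses must be non-negative")


def _label_mask(label_map: CellLabelMap, label: int) -> np.ndarray:
    if label <= 0:
        raise KeyError(f"label ids are positive (got {label})")
    mask = label_map.labels == label
    if not mask.any():
        raise KeyError(f"label {label} not present in the label map")
    return mask


def region_area_um2(label_map: CellLabelMap, label: int, pixel_size_xy: float) -> float:
    """Area of one labelled region: pixel count x (µm/px)²."""
    if pixel_size_xy <= 0:
        raise ValueError("pixel_size_xy must be positive")
    mask = _label_mask(label_map, label)
    return float(mask.sum()) * pixel_size_xy**2


def _contour_perimeter(mask: np.ndarray) -> float:
    """Perimeter of a binary mask, px: simplified marching-squares contour
    length (tolerance scaled to the region's linear size)."""
    area = int(mask.sum())
    tol = max(_DP_TOL_FLOOR, _DP_TOL_COEFF * np.sqrt(area))
    padded = np.pad(mask.astype(np.float64), 2)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise ValueError("degenerate region: no half-level contour")
    total = 0.0
    for c in contours:
        poly = approximate_polygon(c, tolerance=tol)
        d = np.diff(poly, axis=0)
        total += float(np.sqrt((d**2).sum(axis=1)).sum())
    return total


def mask_roundness(mask: np.ndarray) -> float:
    """Circularity 4πA/P² of a binary mask, clamped to <= 1."""
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area < 5:
        raise ValueError("region too small for a roundness estimate (< 5 px)")
    perim = _contour_perimeter(mask)
    if perim <= 0:
        raise ValueError("degenerate region: zero perimeter")
    return min(1.0, 4.0 * np.pi * area / perim**2)


def region_roundness(label_map: CellLabelMap, label: int) -> float:
    """Roundness (clamped circularity) of one labelled region; 1 = disk,
    lower = more elongated."""
    return mask_roundness(_label_mask(label_map, label))


def flag_large_cells(records: list[CellRecord], area_threshold: float = LARGE_CELL_AREA_UM2) -> list[CellRecord]:
    """Subset of records with area strictly greater than the threshold
    (the screen's 'larger than 500 µm²' rule), order preserved."""
    return [r for r in records if r.area_um2 > area_threshold]


def extract_cell_records(
    label_map: CellLabelMap,
    pixel_size_xy: float,
    ser_per_label: dict[int, tuple[float, float]] | None = None,
    min_pixels: int = 5,
) -> list[CellRecord]:
    """Measure every label in a label map.

    Labels smaller than ``min_pixels`` or with a degenerate boundary are
    skipped.  ``ser_per_label`` optionally merges per-cell texture values
    (see :func:`chondroscreen.texture.per_cell_ser`).
    """
    if pixel_size_xy <= 0:
        raise ValueError("pixel_size_xy must be positive")
    records: list[CellRecord] = []
    slices = find_objects(label_map.labels)
    for label, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        mask = label_map.labels[sl] == label
        npx = int(mask.sum())
        if npx < min_pixels:
            continue
        try:
            perim_px = _contour_perimeter(mask)
            roundness = min(1.0, 4.0 * np.pi * npx / perim_px**2)
        except ValueError:
            continue
        spot, ridge = (ser_per_label or {}).get(label, (0.0, 0.0))
        records.append(
            CellRecord(
                well=label_map.well,
                field=label_map.field,
                label=label,
                area_um2=npx * pixel_size_xy**2,
                perimeter_um=perim_px * pixel_size_xy,
                roundness=roundness,
                ser_spot=spot,
                ser_ridge=ridge,
            )
        )
    return records


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """CellRecord list -> DataFrame with a fixed column order."""
    cols = ["well", "field", "label", "area_um2", "perimeter_um", "roundness", "ser_spot", "ser_ridge"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
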