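"""End-to-end analysis steps composed from the per-stage modules.

These are the functions the CLI drives: stack -> per-cell features
(morphology mode), stack -> plane profile (migration mode), and per-well
aggregate tables -> QC / hit / dose outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ImageStack, VoxelGeometry
from .migration import ASSESSMENT_PLANES, PlaneProfile, plane_counts
from .morphology import CellRecord, extract_cell_records
from .segmentation import (
    CellLabelMap,
    detect_nuclei_3d,
    halfmax_refine,
    max_projection,
    segment_cells,
)
from .stats import coefficient_of_variation, qc_gate, QCReport
from .texture import per_cell_ser, ser_maps

__all__ = [
    "analyze_morphology_stack",
    "analyze_migration_stack",
    "control_cv_report",
]


def analyze_morphology_stack(
    stack: ImageStack,
    well: str = "",
    field: int = 0,
    min_sigma: float = 3.0,
    max_sigma: float = 6.0,
    detect_threshold: float = 0.1,
    min_area_px: int = 50,
    ser_scale: float = 3.0,
    refine_fraction: float | None = 0.5,
) -> tuple[list[CellRecord], CellLabelMap]:
    """Morphology-mode stack -> per-cell records.

    Detects nuclei in 3D as segmentation seeds, segments cell footprints on
    the cytoplasm max projection (Otsu + seeded watershed, then a per-cell
    half-maximum refinement so areas track the calibration contour), measures
    area/roundness, and — when an actin channel is present — aggregates
    spot/ridge texture per cell.  Pass ``refine_fraction=None`` to measure on
    the raw watershed partition instead.
    """
    detections = detect_nuclei_3d(
        stack, min_sigma=min_sigma, max_sigma=max_sigma, threshold=detect_threshold
    )
    seeds = [(d.centroid_xyz[0], d.centroid_xyz[1]) for d in detections]
    projection = max_projection(stack, "cytoplasm")
    label_map = segment_cells(projection, seeds, min_area_px=min_area_px)
    if refine_fraction is not None and label_map.n_labels:
        label_map = halfmax_refine(label_map, projection, fraction=refine_fraction)
    label_map.well, label_map.field = well, field

    ser: dict[int, tuple[float, float]] | None = None
    if "actin" in stack.channels:
        actin_proj = max_projection(stack, "actin")
        maps = ser_maps(actin_proj, scale=ser_scale, normalization="kernel")
        ser = per_cell_ser(maps, label_map)
    records = extract_cell_records(
        label_map, stack.geometry.pixel_size_xy, ser_per_label=ser
    )
    return records, label_map


def analyze_migration_stack(
    stack: ImageStack,
    well: str = "",
    min_sigma: float = 3.0,
    max_sigma: float = 6.0,
    detect_threshold: float = 0.1,
) -> PlaneProfile:
    """Migration-mode stack (nuclei channel, 102 planes) -> per-plane
    nucleus-count profile."""
    detections = detect_nuclei_3d(
        stack, min_sigma=min_sigma, max_sigma=max_sigma, threshold=detect_threshold
    )
    return plane_counts(
        detections, stack.geometry.n_planes, well=well, z_step=stack.geometry.z_step
    )


def control_cv_report(
    summaries: pd.DataFrame,
    parameters: tuple[str, ...] = ("mean_area_um2", "mean_roundness"),
    threshold: float = 20.0,
) -> QCReport:
    """Reproducibility gate over control wells: CV% of each parameter across
    the replicate wells of each control condition."""
    entries: dict[str, float] = {}
    for role, pretty in (("negative", "basal"), ("positive", "chondro")):
        sub = summaries[summaries["role"] == role]
        if len(sub) < 2:
            continue
        for param in parameters:
            short = param.replace("mean_", "").replace("_um2", "")
            entries[f"{pretty}/{short}"] = coefficient_of_variation(sub[param])
    return qc_gate(entries, threshold=threshold)
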