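"""Chondrogenic-marker readouts: SOX9 positivity, Collagen II signal, and
comparative-ΔCt qPCR fold changes.

The ΔΔCt convention here: ΔCt = Ct(target) - Ct(reference housekeeping gene)
per sample; ΔΔCt = mean ΔCt(treated) - mean ΔCt(control); fold change =
2^(-ΔΔCt).  Group means (not per-sample pairing) are used; switch with
``paired=True`` when samples are genuinely paired.  No amplification-
efficiency correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .segmentation import CellLabelMap

__all__ = [
    "QPCRSample",
    "percent_positive",
    "mean_marker_signal",
    "otsu_positivity_threshold",
    "ddct_fold_change",
    "ddct_table",
]


@dataclass(frozen=True)
class QPCRSample:
    """One qPCR measurement: target and reference Ct values."""

    ct_target: float
    ct_reference: float
    group: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive (got {v})")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def mean_marker_signal(cell_labels: CellLabelMap, marker_image: np.ndarray) -> dict[int, float]:
    """Per-label mean marker intensity (background label 0 excluded)."""
    marker = np.asarray(marker_image, dtype=float)
    if marker.shape != cell_labels.labels.shape:
        raise ValueError(
            f"marker image {marker.shape} and label map {cell_labels.labels.shape} differ in shape"
        )
    ids = cell_labels.label_ids()
    if len(ids) == 0:
        return {}
    means = ndi.mean(marker, labels=cell_labels.labels, index=ids)
    return {int(k): float(m) for k, m in zip(ids, means)}


def otsu_positivity_threshold(per_label_means: dict[int, float]) -> float:
    """Data-driven positivity threshold: Otsu on the per-nucleus mean
    intensities.  Requires at least two distinct values."""
    values = np.asarray(list(per_label_means.values()), dtype=float)
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError("need at least two distinct per-label means for Otsu")
    return float(threshold_otsu(values))


def percent_positive(
    nuclei_labels: CellLabelMap,
    marker_image: np.ndarray,
    intensity_threshold: float,
) -> float:
    """Percentage of labelled nuclei whose mean marker intensity strictly
    exceeds the threshold."""
    means = mean_marker_signal(nuclei_labels, marker_image)
    if not means:
        raise ValueError("no labelled nuclei")
    positive = sum(1 for v in means.values() if v > intensity_threshold)
    return 100.0 * positive / len(means)


def ddct_fold_change(
    treated: Sequence[QPCRSample],
    control: Sequence[QPCRSample],
    paired: bool = False,
) -> float:
    """Comparative-ΔCt fold change of treated over control, 2^(-ΔΔCt).

    ΔΔCt = 0 gives fold 1; each cycle of earlier target amplification
    (ΔΔCt = -1) doubles the fold change.
    """
    if not treated or not control:
        raise ValueError("both groups must be non-empty")
    dt = np.array([s.delta_ct for s in treated], dtype=float)
    dc = np.array([s.delta_ct for s in control], dtype=float)
    if paired:
        if len(dt) != len(dc):
            raise ValueError("paired ΔΔCt needs equal group sizes")
        ddct = float(np.mean(dt - dc))
    else:
        ddct = float(dt.mean() - dc.mean())
    return float(2.0 ** (-ddct))


def ddct_table(samples: Sequence[QPCRSample], control_group: str = "control") -> pd.DataFrame:
    """Tidy per-sample ΔCt table plus the group-level ΔΔCt/fold summary.

    Returns one row per sample with its ΔCt, annotated with the group's
    ΔΔCt relative to ``control_group`` and the corresponding fold change.
    """
    if not samples:
        raise ValueError("no samples")
    df = pd.DataFrame(
        {
            "group": [s.group for s in samples],
            "replicate": [s.replicate for s in samples],
            "ct_target": [s.ct_target for s in samples],
            "ct_reference": [s.ct_reference for s in samples],
            "delta_ct": [s.delta_ct for s in samples],
        }
    )
    if control_group not in set(df["group"]):
        raise ValueError(f"control group {control_group!r} not among samples")
    control_mean = df.loc[df["group"] == control_group, "delta_ct"].mean()
    group_means = df.groupby("group")["delta_ct"].mean()
    df["ddct"] = df["group"].map(group_means) - control_mean
    df["fold_change"] = 2.0 ** (-df["ddct"])
    return df
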