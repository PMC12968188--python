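"""Per-plane nuclei profiles, migration and proliferation statistics.

The screen's endpoint motility measure is a depth sampling, not a census:
nuclei are counted at five fixed assessment planes (20, 40, 60, 80, 100,
i.e. 100-500 µm at a 5 µm z-step) and summed.  Each nucleus is assigned to
exactly one plane (the nearest plane of its 3D centroid), so the five plane
counts are disjoint and the statistic never exceeds the total nucleus count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import NucleusDetection

__all__ = [
    "PlaneProfile",
    "plane_counts",
    "plane_depth",
    "migration_statistic",
    "total_nuclei",
    "flag_migration_hits",
    "ASSESSMENT_PLANES",
    "MIGRATION_COUNT_THRESHOLD",
]

#: default depth-assessment planes (100, 200, 300, 400, 500 µm at 5 µm steps)
ASSESSMENT_PLANES = (20, 40, 60, 80, 100)

#: wells with strictly more migrated nuclei than this are selected
MIGRATION_COUNT_THRESHOLD = 200


@dataclass
class PlaneProfile:
    """Nuclei counts per z-plane for one well."""

    well: str
    counts: np.ndarray
    z_step: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1D vector")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        self.counts = counts

    @property
    def n_planes(self) -> int:
        return len(self.counts)

    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_planes) * self.z_step


def plane_counts(
    detections: list[NucleusDetection],
    n_planes: int,
    well: str = "",
    z_step: float = 5.0,
) -> PlaneProfile:
    """Histogram detections into per-plane counts.

    Every detection lands in exactly one plane; the counts sum to the number
    of detections.
    """
    counts = np.zeros(n_planes, dtype=np.int64)
    for d in detections:
        if not (0 <= d.z_plane < n_planes):
            raise ValueError(f"detection at plane {d.z_plane} outside [0, {n_planes})")
        counts[d.z_plane] += 1
    return PlaneProfile(well=well, counts=counts, z_step=z_step)


def plane_depth(plane_index: int, z_step: float) -> float:
    """Depth below the gel floor of a plane: index x z-step (µm).
    Plane 20 at a 5 µm step is 100 µm deep."""
    if plane_index < 0:
        raise ValueError("plane index must be non-negative")
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    return plane_index * z_step


def migration_statistic(
    profile: PlaneProfile,
    assessment_planes: tuple[int, ...] = ASSESSMENT_PLANES,
) -> int:
    """Sum of nuclei counts at the depth-assessment planes."""
    for p in assessment_planes:
        if not (0 <= p < profile.n_planes):
            raise ValueError(f"assessment plane {p} outside the profile ({profile.n_planes} planes)")
    return int(profile.counts[list(assessment_planes)].sum())


def total_nuclei(profile: PlaneProfile) -> int:
    """Total nucleus count over all planes — the screen's proliferation
    readout (one nucleus = one cell)."""
    return int(profile.counts.sum())


def flag_migration_hits(
    summaries: dict[str, int],
    threshold: int = MIGRATION_COUNT_THRESHOLD,
) -> set[str]:
    """Wells whose migration count strictly exceeds the threshold
    ('more than 200 cell migrations')."""
    return {well for well, count in summaries.items() if count > threshold}


def profiles_to_frame(profiles: list[PlaneProfile]) -> pd.DataFrame:
    """Profiles -> wide DataFrame (well, plane_0 ... plane_{n-1})."""
    if not profiles:
        return pd.DataFrame(columns=["well"])
    n = profiles[0].n_planes
    rows = []
    for p in profiles:
        if p.n_planes != n:
            raise ValueError("profiles differ in plane count")
        rows.append({"well": p.well, **{f"plane_{i}": int(c) for i, c in enumerate(p.counts)}})
    return pd.DataFrame(rows)


def summarize_profiles(
    profiles: list[PlaneProfile],
    assessment_planes: tuple[int, ...] = ASSESSMENT_PLANES,
) -> pd.DataFrame:
    """Per-well summary: total nuclei, migration statistic, assessment depths."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "well": p.well,
                "total_nuclei": total_nuclei(p),
                "migration_count": migration_statistic(p, assessment_planes),
                "assessment_depths_um": ";".join(
                    f"{plane_depth(i, p.z_step):g}" for i in assessment_planes
                ),
            }
        )
    return pd.DataFrame(rows)
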