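"""Nucleus detection in 3D z-stacks and cell-footprint segmentation.

Nuclei are found with multiscale scale-normalized Laplacian-of-Gaussian blob
detection in 3D, with the axial blur scaled by an anisotropy factor (axial
sigma / lateral sigma in voxel units) and a threshold expressed relative to
the maximum response, so detection counts are invariant under uniform
intensity scaling.  Cell footprints are segmented in 2D (max-intensity
projection of the cytoplasm channel) by Otsu thresholding plus a seeded
watershed from the nucleus positions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .io import ImageStack

__all__ = [
    "NucleusDetection",
    "CellLabelMap",
    "detect_nuclei_3d",
    "segment_cells",
    "halfmax_refine",
    "max_projection",
    "match_detections",
]

#: default axial/lateral sigma ratio in voxel units (1 plane vs 4 px)
DEFAULT_Z_ANISOTROPY = 0.25


@dataclass(frozen=True)
class NucleusDetection:
    """One detected nucleus: continuous voxel coordinates (x, y, z), the
    nearest integer plane, and the (positive) blob-detector response."""

    centroid_xyz: tuple[float, float, float]
    z_plane: int
    response: float

    def __post_init__(self) -> None:
        if self.z_plane < 0:
            raise ValueError("z_plane must be non-negative")
        if self.response <= 0:
            raise ValueError("response must be positive")


@dataclass
class CellLabelMap:
    """2D integer label image: 0 = background, k > 0 = cell k (labels are
    contiguous, 8-connected components)."""

    labels: np.ndarray
    well: str = ""
    field: int = 0

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def detect_nuclei_3d(
    stack: ImageStack,
    min_sigma: float = 3.0,
    max_sigma: float = 6.0,
    threshold: float = 0.15,
    n_scales: int = 4,
    z_anisotropy: float = DEFAULT_Z_ANISOTROPY,
    border_px: int = 4,
) -> list[NucleusDetection]:
    """Detect nuclei in the 3D nuclei channel by multiscale LoG blob detection.

    Parameters
    ----------
    min_sigma, max_sigma : float
        Lateral blob scales (px) bracketing the expected nucleus size; the
        axial sigma is ``sigma * z_anisotropy`` planes.
    threshold : float
        Relative threshold: keep maxima above ``threshold * max(response)``.
    z_anisotropy : float
        Axial/lateral sigma ratio in voxel units.
    border_px : int
        Lateral exclusion margin: maxima within this many px of the xy image
        border are discarded (partially-imaged objects and filter edge
        artifacts).  The z borders stay live — cells sit at the gel floor.

    Returns
    -------
    list of NucleusDetection, sorted by z_plane then descending response.
    Duplicate responses within a radius of ``max_sigma`` (anisotropy-
    normalized) are suppressed, strongest first.
    """
    if min_sigma >= max_sigma:
        raise ValueError("min_sigma must be < max_sigma")
    if not (0 < threshold < 1):
        raise ValueError("threshold is a fraction of the maximum response")
    img = stack.channel("nuclei").astype(np.float64)
    if not np.any(img > 0):
        return []

    sigmas = np.geomspace(min_sigma, max_sigma, n_scales)
    best = None
    for s in sigmas:
        # scale-normalized negative LoG: bright blobs -> positive peaks
        resp = -(s**2) * ndi.gaussian_laplace(img, sigma=(s * z_anisotropy, s, s))
        best = resp if best is None else np.maximum(best, resp)

    peak = float(best.max())
    if peak <= 0:
        return []
    footprint = np.ones((3, 5, 5), dtype=bool)
    local_max = (best == ndi.maximum_filter(best, footprint=footprint)) & (
        best > threshold * peak
    )
    if border_px > 0:
        local_max[:, :border_px, :] = False
        local_max[:, -border_px:, :] = False
        local_max[:, :, :border_px] = False
        local_max[:, :, -border_px:] = False
    zc, yc, xc = np.nonzero(local_max)
    resp = best[zc, yc, xc]
    order = np.argsort(resp)[::-1]
    zc, yc, xc, resp = zc[order], yc[order], xc[order], resp[order]

    # greedy non-maximum suppression in anisotropy-normalized space
    coords = np.column_stack([xc, yc, zc / z_anisotropy]).astype(float)
    tree = cKDTree(coords)
    keep = np.ones(len(coords), dtype=bool)
    for i in range(len(coords)):
        if not keep[i]:
            continue
        for j in tree.query_ball_point(coords[i], r=max_sigma):
            if j != i and resp[j] <= resp[i]:
                keep[j] = False
    detections = [
        NucleusDetection(
            centroid_xyz=(float(x), float(y), float(z)),
            z_plane=int(z),
            response=float(r),
        )
        for x, y, z, r in zip(xc[keep], yc[keep], zc[keep], resp[keep])
    ]
    detections.sort(key=lambda d: (d.z_plane, -d.response))
    return detections


def max_projection(stack: ImageStack, channel: str = "cytoplasm") -> np.ndarray:
    """Max-intensity projection of a channel along z."""
    return stack.channel(channel).max(axis=0)


def segment_cells(
    image: np.ndarray,
    seeds: list[tuple[float, float]],
    min_area_px: int = 50,
) -> CellLabelMap:
    """Partition the thresholded cytoplasm image into seeded cell labels.

    The foreground mask is Otsu-thresholded; a watershed grown from the seed
    points (nucleus positions, (x, y)) partitions it, so touching cells split
    along intensity valleys.  Foreground components containing no seed are
    dropped, as are labels smaller than ``min_area_px``.  Labels are
    renumbered contiguously from 1.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("segment_cells expects a 2D image or projection")
    H, W = image.shape
    if not seeds:
        warnings.warn("segment_cells called with no seeds; returning empty label map")
        return CellLabelMap(labels=np.zeros(image.shape, dtype=np.int32))
    for x, y in seeds:
        if not (0 <= x < W and 0 <= y < H):
            raise ValueError(f"seed ({x}, {y}) outside the image {image.shape}")
    if image.max() <= image.min():
        return CellLabelMap(labels=np.zeros(image.shape, dtype=np.int32))
    mask = image > threshold_otsu(image)
    markers = np.zeros(image.shape, dtype=np.int32)
    for k, (x, y) in enumerate(seeds, start=1):
        markers[int(round(y)), int(round(x))] = k
    labels = watershed(-image, markers=markers, mask=mask, connectivity=2)
    # drop undersized labels, renumber contiguously
    out = np.zeros_like(labels)
    next_id = 1
    for k in np.unique(labels):
        if k == 0:
            continue
        region = labels == k
        if int(region.sum()) < min_area_px:
            continue
        out[region] = next_id
        next_id += 1
    return CellLabelMap(labels=out)


def halfmax_refine(
    label_map: CellLabelMap,
    image: np.ndarray,
    fraction: float = 0.5,
    min_area_px: int = 25,
) -> CellLabelMap:
    """Shrink each watershed label to its pixels above a per-cell relative
    intensity threshold (``fraction`` of that cell's own maximum).

    The global Otsu mask captures where cells are, but its cut depends on the
    field's overall brightness mix; a per-cell half-maximum cut makes the
    measured footprint independent of staining amplitude, which is the
    contour the area calibration is defined on.  Labels falling below
    ``min_area_px`` after refinement are dropped; surviving ids are kept.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != label_map.labels.shape:
        raise ValueError("image and label map differ in shape")
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    out = np.zeros_like(label_map.labels)
    for k in label_map.label_ids():
        region = label_map.labels == k
        cut = fraction * image[region].max()
        core = region & (image > cut)
        if int(core.sum()) >= min_area_px:
            out[core] = k
    return CellLabelMap(labels=out, well=label_map.well, field=label_map.field)


def match_detections(
    detections: list[NucleusDetection],
    truth_xyz: np.ndarray,
    max_dist: float = 2.0,
) -> tuple[int, int, int]:
    """1:1 Hungarian matching of detections against planted centroids.

    Distances are Euclidean in voxel index space (x, y in px; z in planes).
    Returns (n_matched, n_false_positive, n_missed); precision and recall
    follow.
    """
    from scipy.optimize import linear_sum_assignment

    truth_xyz = np.asarray(truth_xyz, dtype=float)
    if len(detections) == 0:
        return 0, 0, len(truth_xyz)
    if len(truth_xyz) == 0:
        return 0, len(detections), 0
    det = np.array([d.centroid_xyz for d in detections], dtype=float)
    cost = np.linalg.norm(det[:, None, :] - truth_xyz[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(cost)
    matched = int(np.sum(cost[ri, ci] <= max_dist))
    return matched, len(detections) - matched, len(truth_xyz) - matched
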