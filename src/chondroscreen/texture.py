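"""SER-style spot/ridge texture features on the actin channel.

The commercial "Structure Element Recognition" (SER) texture family is
proprietary; this module provides a functional equivalent built on the
Hessian of a Gaussian-smoothed image.  With eigenvalues λ1 >= λ2 of the 2D
Hessian at scale σ (Gaussian-derivative convolution, not finite
differences):

* **spot** response = -(λ1 + λ2) where both eigenvalues are negative (an
  intensity peak curving down in every direction), else 0;
* **ridge** response = -λ2 * (1 - |λ1| / |λ2|) where λ2 < 0 and |λ2| > |λ1|
  (one dominant negative curvature across an elongated bright structure),
  else 0.

With *kernel normalization* the input is first divided by its
Gaussian-weighted local mean (same σ), which makes both responses exactly
invariant to global intensity scaling — staining brightness cancels.
Bright-on-dark polarity is assumed (phalloidin is bright); the dark-feature
duals (hole, valley) are provided for completeness but unused by the
pipeline.  Per-cell values are the mean response over the cell's pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .segmentation import CellLabelMap

__all__ = ["TextureMaps", "ser_maps", "per_cell_ser", "SER_SCALE_PX"]

#: default texture scale, px (Gaussian sigma)
SER_SCALE_PX = 3.0


@dataclass
class TextureMaps:
    """Spot and ridge response maps for one 2D image."""

    spot: np.ndarray
    ridge: np.ndarray
    hole: np.ndarray
    valley: np.ndarray
    scale: float
    normalization: str

    def __post_init__(self) -> None:
        if self.spot.shape != self.ridge.shape:
            raise ValueError("response maps must share one shape")
        if self.normalization not in ("kernel", "none"):
            raise ValueError("normalization must be 'kernel' or 'none'")


def _second_derivative_kernel_bias(sigma: float) -> float:
    """Sum of the truncated discrete Gaussian second-derivative kernel.

    The continuous kernel integrates to zero but scipy's truncated sampled
    kernel does not quite, so a constant image picks up a spurious curvature
    proportional to its level; this bias is subtracted in :func:`_hessian`.
    """
    n = int(4.0 * sigma + 0.5) * 2 + 9
    probe = np.zeros(n)
    probe[n // 2] = 1.0
    kernel = ndi.gaussian_filter1d(probe, sigma, order=2, mode="constant")
    return float(kernel.sum())


def _hessian(image: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-derivative Hessian components (Hxx, Hxy, Hyy), axis order
    (row=y, col=x), corrected for the truncated kernel's DC bias so a
    constant image has exactly zero curvature."""
    hyy = ndi.gaussian_filter(image, sigma, order=(2, 0), mode="nearest")
    hxx = ndi.gaussian_filter(image, sigma, order=(0, 2), mode="nearest")
    hxy = ndi.gaussian_filter(image, sigma, order=(1, 1), mode="nearest")
    bias = _second_derivative_kernel_bias(sigma)
    if bias != 0.0:
        smooth = ndi.gaussian_filter(image, sigma, mode="nearest")
        hxx = hxx - bias * smooth
        hyy = hyy - bias * smooth
    return hxx, hxy, hyy


def ser_maps(
    image: np.ndarray,
    scale: float = SER_SCALE_PX,
    normalization: str = "kernel",
) -> TextureMaps:
    """Compute spot/ridge (and hole/valley) texture response maps.

    Parameters
    ----------
    image : 2D array
        Single-channel actin image (or any 2D grid).
    scale : float
        Gaussian sigma used both for the local-mean normalization kernel and
        for the Hessian derivatives, px.
    normalization : {'kernel', 'none'}
        'kernel' divides by the Gaussian local mean before differentiation,
        making responses invariant to global intensity scale.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("ser_maps expects a 2D image")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if min(img.shape) < 2 * scale:
        raise ValueError(f"image {img.shape} smaller than the kernel support (2 x scale)")
    if normalization not in ("kernel", "none"):
        raise ValueError("normalization must be 'kernel' or 'none'")

    if normalization == "kernel":
        local_mean = ndi.gaussian_filter(img, scale, mode="nearest")
        img = np.divide(img, local_mean, out=np.ones_like(img), where=local_mean > 0)

    hxx, hxy, hyy = _hessian(img, scale)
    # eigenvalues of [[hxx, hxy], [hxy, hyy]]; l1 >= l2
    tr = hxx + hyy
    disc = np.sqrt(np.maximum((hxx - hyy) ** 2 + 4 * hxy**2, 0.0))
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    # curvature below numerical noise (relative to the image magnitude) is
    # flat, not structure: a constant image must yield exactly zero responses
    tol = 1e-12 * float(np.mean(np.abs(img)) + 1e-300)
    l1 = np.where(np.abs(l1) < tol, 0.0, l1)
    l2 = np.where(np.abs(l2) < tol, 0.0, l2)

    both_neg = (l1 < 0) & (l2 < 0)
    spot = np.where(both_neg, -(l1 + l2), 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        aniso = 1.0 - np.abs(l1) / np.abs(l2)
    ridge_like = (l2 < 0) & (np.abs(l2) > np.abs(l1))
    ridge = np.where(ridge_like, -l2 * np.where(ridge_like, aniso, 0.0), 0.0)
    ridge = np.maximum(ridge, 0.0)

    # dark-feature duals (unused by the screen pipeline)
    both_pos = (l1 > 0) & (l2 > 0)
    hole = np.where(both_pos, l1 + l2, 0.0)
    valley_like = (l1 > 0) & (np.abs(l1) > np.abs(l2))
    with np.errstate(divide="ignore", invalid="ignore"):
        vaniso = 1.0 - np.abs(l2) / np.abs(l1)
    valley = np.where(valley_like, l1 * np.where(valley_like, vaniso, 0.0), 0.0)
    valley = np.maximum(valley, 0.0)

    return TextureMaps(
        spot=spot, ridge=ridge, hole=hole, valley=valley,
        scale=scale, normalization=normalization,
    )


def per_cell_ser(maps: TextureMaps, label_map: CellLabelMap) -> dict[int, tuple[float, float]]:
    """Mean spot and ridge response over each label's pixels.

    Returns ``{label: (ser_spot, ser_ridge)}``; each aggregate depends only
    on its own label's pixels.
    """
    if maps.spot.shape != label_map.labels.shape:
        raise ValueError(
            f"texture maps {maps.spot.shape} and label map {label_map.labels.shape} differ in shape"
        )
    labels = label_map.labels
    ids = label_map.label_ids()
    if len(ids) == 0:
        return {}
    spot_means = ndi.mean(maps.spot, labels=labels, index=ids)
    ridge_means = ndi.mean(maps.ridge, labels=labels, index=ids)
    return {int(k): (float(s), float(r)) for k, s, r in zip(ids, spot_means, ridge_means)}
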