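"""Ground-truthed synthetic plates for the 3D chondrogenesis screen.

The generator emulates the screen's measurement model: ~3x10^4 bone-marrow
stromal cells seeded at the floor of a ~500 µm hydrogel column in each well of
a 96-well plate, imaged as 3-channel confocal z-stacks (nuclei / cytoplasm /
actin).  A condition-dependent fraction of cells migrates up through the gel;
condition also sets the cell-footprint area and elongation (basal cells are
small and round, chondrogenic-media cells large and spindle-shaped) and the
actin texture class (punctate vs fibrous).

Two layers are provided:

* a **rendering layer** (:func:`generate_field_stack`,
  :func:`generate_plate_dataset`) that rasterizes one field of view per well
  into an :class:`~chondroscreen.io.ImageStack`, for validating the image
  algorithms against planted ground truth; and
* an **aggregate layer** (:func:`sample_well_summaries`) that draws whole-well
  summary statistics (mean area, mean roundness, migration counts) directly
  from the condition's effect model, for exercising plate QC, hit calling and
  dose-response statistics at the full per-well cell count.

Everything is driven by explicit seeds; per-well substreams are keyed by
(seed, row, col) so outputs do not depend on well iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ImageStack,
    PlateLayout,
    PLATE_MAP_COLUMNS,
    VoxelGeometry,
    well_address,
    well_name,
)

__all__ = [
    "GroundTruthCell",
    "EffectModel",
    "PlateSpec",
    "TEXTURE_CLASSES",
    "basal_effect",
    "chondro_effect",
    "trametinib_like_effect",
    "migratory_effect",
    "default_effects",
    "screen_plate_spec",
    "dose_plate_spec",
    "sample_truth_cells",
    "generate_field_stack",
    "generate_plate_dataset",
    "sample_well_summaries",
    "ellipse_circularity",
    "write_ground_truth",
    "read_ground_truth",
]

TEXTURE_CLASSES = ("spot", "ridge", "mixed", "flat")

#: default nucleus render model: isotropic-in-xy 3D Gaussian
NUCLEUS_SIGMA_XY = 4.0  # px
NUCLEUS_SIGMA_Z = 1.0   # planes
NUCLEUS_AMPLITUDE = 1000.0
CYTO_AMPLITUDE = 800.0

#: growth area of a 96-well plate well (0.32 cm^2), µm^2 — used to scale a
#: whole-well cell count down to one rendered field of view
WELL_AREA_UM2 = 3.2e7

_2LN2 = 2.0 * math.log(2.0)


def ellipse_circularity(aspect_ratio: float) -> float:
    """Circularity 4πA/P² of an ideal ellipse with the given axis ratio.

    Uses Ramanujan's perimeter approximation; equals 1 for a disk and
    decreases with elongation (≈0.66 at 3:1).  This is the map the generator
    uses to translate planted aspect ratios into expected roundness.
    """
    r = float(aspect_ratio)
    if r < 1:
        raise ValueError("aspect ratio must be >= 1")
    denom = 3.0 * (r + 1.0) - math.sqrt((3.0 * r + 1.0) * (r + 3.0))
    return 4.0 * r / denom**2


@dataclass(frozen=True)
class GroundTruthCell:
    """Latent per-cell quantities the assay is supposed to measure.

    ``centroid_xyz`` is (x, y, z) in continuous voxel coordinates (x = column,
    y = row, z = plane index); ``z_plane`` is the integer plane holding the
    nucleus centre; ``nominal_area`` is the target 2D cytoplasm footprint in
    µm²; ``aspect_ratio`` >= 1 (1 = disk).
    """

    centroid_xyz: tuple[float, float, float]
    nominal_area: float
    aspect_ratio: float
    z_plane: int
    texture_class: str
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.nominal_area <= 0:
            raise ValueError("nominal_area must be positive")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")
        if self.z_plane < 0:
            raise ValueError("z_plane must be non-negative")
        if self.texture_class not in TEXTURE_CLASSES:
            raise ValueError(f"texture_class must be one of {TEXTURE_CLASSES}")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")


@dataclass(frozen=True)
class EffectModel:
    """Per-condition sampling distributions for the latent cell quantities.

    Cell-level moments (area, aspect) are supplemented by well-level
    coefficients of variation (``well_cv_*``): plate replicates of the same
    condition differ by a multiplicative well effect, which is what the
    screen's CV-based QC gate actually measures (cell-sampling noise is
    negligible at ~3x10^4 cells/well).
    """

    area_um2_mean: float
    area_um2_sd: float
    aspect_mean: float
    aspect_sd: float
    migrated_fraction: float
    texture_weights: Mapping[str, float]
    n_cells_mean: float = 30_000.0
    n_cells_sd: float = 3_000.0
    well_cv_area: float = 0.11
    well_cv_roundness: float = 0.027
    floor_planes: tuple[int, int] = (0, 5)
    migration_planes: tuple[int, int] = (10, 100)

    def __post_init__(self) -> None:
        for name in ("area_um2_sd", "aspect_sd", "n_cells_sd", "well_cv_area", "well_cv_roundness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.migrated_fraction <= 1.0):
            raise ValueError("migrated_fraction must lie in [0, 1]")
        w = dict(self.texture_weights)
        unknown = set(w) - set(TEXTURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown texture classes: {sorted(unknown)}")
        total = sum(w.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"texture weights must sum to 1 (got {total})")
        object.__setattr__(self, "texture_weights", w)

    @property
    def roundness_mean(self) -> float:
        """Expected roundness implied by the aspect-ratio distribution."""
        return ellipse_circularity(self.aspect_mean)

    @property
    def roundness_sd(self) -> float:
        # delta method through the ellipse-circularity map
        eps = 1e-4
        d = (ellipse_circularity(self.aspect_mean + eps) - ellipse_circularity(max(1.0, self.aspect_mean - eps))) / (2 * eps)
        return abs(d) * self.aspect_sd


def basal_effect() -> EffectModel:
    """Basal (negative-control) medium: small, rounded cells (~230 µm²,
    roundness ~0.78), the larger migrating fraction, fibrous/ridge-leaning
    actin (spread cells with stress fibres)."""
    return EffectModel(
        area_um2_mean=231.6, area_um2_sd=55.0,
        aspect_mean=2.35, aspect_sd=0.30,
        migrated_fraction=0.25,
        texture_weights={"ridge": 0.7, "mixed": 0.2, "spot": 0.1},
        well_cv_area=0.11, well_cv_roundness=0.027,
    )


def chondro_effect() -> EffectModel:
    """Chondrogenic (positive-control) medium: large, elongated
    chondroprogenitor-like cells (~694 µm², roundness ~0.64), reduced
    migration, punctate/spot-leaning actin (depolymerised cytoskeleton)."""
    return EffectModel(
        area_um2_mean=694.4, area_um2_sd=140.0,
        aspect_mean=3.20, aspect_sd=0.35,
        migrated_fraction=0.10,
        texture_weights={"spot": 0.7, "mixed": 0.2, "ridge": 0.1},
        well_cv_area=0.18, well_cv_roundness=0.031,
    )


def trametinib_like_effect() -> EffectModel:
    """A chondro-mimetic compound: area ~657 µm², roundness ~0.62, texture
    close to the chondrogenic condition."""
    return EffectModel(
        area_um2_mean=656.7, area_um2_sd=140.0,
        aspect_mean=3.30, aspect_sd=0.35,
        migrated_fraction=0.12,
        texture_weights={"spot": 0.65, "mixed": 0.25, "ridge": 0.1},
        well_cv_area=0.10, well_cv_roundness=0.020,
    )


def migratory_effect() -> EffectModel:
    """A motility-enhancing compound (cytoskeletal disruptor): basal-like
    morphology with a much larger migrating fraction."""
    return replace(basal_effect(), migrated_fraction=0.45)


def default_effects() -> dict[str, EffectModel]:
    """Condition-keyed effect models for the default synthetic screen."""
    return {"negative": basal_effect(), "positive": chondro_effect()}


def benchmark_effects(well_cv_area: float = 0.08, well_cv_roundness: float = 0.02) -> dict[str, EffectModel]:
    """Effect models for hit-calling validation plates: the conditions'
    printed mean areas and roundness with modest, uniform well-level CVs.

    The default models carry each condition's own observed reproducibility,
    which differs between conditions; for benchmarking the *decision rule*
    a uniform modest CV keeps the constructed positive/negative unambiguous.
    """
    return {
        "negative": replace(
            basal_effect(), well_cv_area=well_cv_area, well_cv_roundness=well_cv_roundness
        ),
        "positive": replace(
            chondro_effect(), well_cv_area=well_cv_area, well_cv_roundness=well_cv_roundness
        ),
    }


@dataclass(frozen=True)
class PlateSpec:
    """A plate design: well-to-condition layout plus the master seed."""

    layout: PlateLayout
    rng_seed: int
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self) -> None:
        for w in self.layout.wells:
            r, c = well_address(w)
            if r >= self.n_rows or c >= self.n_cols:
                raise ValueError(f"well {w} outside a {self.n_rows}x{self.n_cols} plate")


def _layout_from_rows(rows: list[dict]) -> PlateLayout:
    t = pd.DataFrame(rows, columns=list(PLATE_MAP_COLUMNS))
    return PlateLayout(table=t)


def _control_rows(n_negative: int, n_positive: int, wells: Iterable[str]) -> list[dict]:
    it = iter(wells)
    rows = []
    for role, n in (("negative", n_negative), ("positive", n_positive)):
        for rep in range(1, n + 1):
            rows.append(
                {"well": next(it), "role": role, "compound_id": None,
                 "concentration_nM": None, "replicate": rep}
            )
    return rows


def _well_sequence(n_rows: int, n_cols: int) -> list[str]:
    return [well_name(r, c) for r in range(n_rows) for c in range(n_cols)]


def screen_plate_spec(
    compounds: Sequence[str],
    concentrations_nM: Sequence[float] = (100.0, 10.0, 1.0),
    replicates: int = 2,
    n_negative: int = 4,
    n_positive: int = 4,
    rng_seed: int = 0,
    n_rows: int = 8,
    n_cols: int = 12,
) -> PlateSpec:
    """Primary-screen design: each compound at three ten-fold concentration
    levels with two replicates, plus basal and chondrogenic control wells."""
    wells = _well_sequence(n_rows, n_cols)
    needed = n_negative + n_positive + len(compounds) * len(concentrations_nM) * replicates
    if needed > len(wells):
        raise ValueError(f"design needs {needed} wells but the plate has {len(wells)}")
    rows = _control_rows(n_negative, n_positive, wells)
    it = iter(wells[len(rows):])
    for comp in compounds:
        for conc in concentrations_nM:
            for rep in range(1, replicates + 1):
                rows.append(
                    {"well": next(it), "role": "compound", "compound_id": comp,
                     "concentration_nM": float(conc), "replicate": rep}
                )
    return PlateSpec(layout=_layout_from_rows(rows), rng_seed=rng_seed, n_rows=n_rows, n_cols=n_cols)


def dose_plate_spec(
    compound: str,
    concentrations_nM: Sequence[float] = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0),
    replicates: int = 4,
    n_negative: int = 4,
    n_positive: int = 4,
    rng_seed: int = 0,
    n_rows: int = 8,
    n_cols: int = 12,
) -> PlateSpec:
    """Eight-point semi-log dose-response design, four replicates per
    concentration, plus control wells."""
    wells = _well_sequence(n_rows, n_cols)
    rows = _control_rows(n_negative, n_positive, wells)
    it = iter(wells[len(rows):])
    for conc in concentrations_nM:
        for rep in range(1, replicates + 1):
            rows.append(
                {"well": next(it), "role": "compound", "compound_id": compound,
                 "concentration_nM": float(conc), "replicate": rep}
            )
    return PlateSpec(layout=_layout_from_rows(rows), rng_seed=rng_seed, n_rows=n_rows, n_cols=n_cols)


def _well_rng(seed: int, well: str, stream: int = 0) -> np.random.Generator:
    r, c = well_address(well)
    return np.random.default_rng(np.random.SeedSequence([int(seed), r, c, stream]))


def _sample_z_plane(effect: EffectModel, n_planes: int, rng: np.random.Generator) -> int:
    """Floor/migrating mixture for migration-mode stacks; near-floor placement
    for shallow morphology-mode stacks."""
    if n_planes <= effect.migration_planes[0]:
        return int(rng.integers(1, max(2, n_planes - 1)))
    if rng.random() < effect.migrated_fraction:
        lo, hi = effect.migration_planes
        return int(rng.integers(lo, min(hi, n_planes - 1) + 1))
    lo, hi = effect.floor_planes
    return int(rng.integers(lo, min(hi, n_planes - 1) + 1))


def sample_truth_cells(
    effect: EffectModel,
    n_cells: int,
    geometry: VoxelGeometry,
    shape: tuple[int, int],
    rng: np.random.Generator,
    min_separation_sigma: float | None = None,
    max_tries: int = 500,
) -> list[GroundTruthCell]:
    """Draw latent cells for one field of view from an effect model.

    ``min_separation_sigma``, if given, enforces a minimum pairwise centroid
    distance of that many nucleus sigmas (anisotropy-normalized), by rejection
    sampling — used to build stacks where every nucleus is resolvable.
    """
    H, W = shape
    cells: list[GroundTruthCell] = []
    placed: list[tuple[float, float, float]] = []
    z_scale = NUCLEUS_SIGMA_XY / NUCLEUS_SIGMA_Z  # planes -> sigma-equivalent px
    for _ in range(n_cells):
        area = float(np.clip(rng.normal(effect.area_um2_mean, effect.area_um2_sd), 40.0, None))
        aspect = float(np.clip(rng.normal(effect.aspect_mean, effect.aspect_sd), 1.0, None))
        area_px = area / geometry.pixel_area_um2
        sx, _ = _footprint_sigmas(area_px, aspect)
        # margin keeps the nucleus and the half-maximum footprint ellipse
        # (semi-major 1.18 sigma) inside the field; faint Gaussian tails may clip
        margin = max(4.0 * NUCLEUS_SIGMA_XY, 1.8 * sx) + 1.0
        if 2 * margin >= min(H, W):
            raise ValueError(
                f"field {shape} too small for a footprint of {area:.0f} µm² at "
                f"{geometry.pixel_size_xy} µm/px"
            )
        for _try in range(max_tries):
            x = rng.uniform(margin, W - margin)
            y = rng.uniform(margin, H - margin)
            zp = _sample_z_plane(effect, geometry.n_planes, rng)
            z = float(zp)
            if min_separation_sigma is None:
                break
            ok = all(
                (x - px) ** 2 + (y - py) ** 2 + ((z - pz) * z_scale) ** 2
                > (min_separation_sigma * NUCLEUS_SIGMA_XY) ** 2
                for px, py, pz in placed
            )
            if ok:
                break
        else:
            raise RuntimeError("could not place cells at the requested separation")
        placed.append((x, y, z))
        tc = rng.choice(
            list(effect.texture_weights), p=list(effect.texture_weights.values())
        )
        inten = float(np.clip(rng.normal(1.0, 0.12), 0.4, None))
        cells.append(
            GroundTruthCell(
                centroid_xyz=(x, y, z),
                nominal_area=area,
                aspect_ratio=aspect,
                z_plane=zp,
                texture_class=str(tc),
                intensity_scale=inten,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# rendering


def _footprint_sigmas(area_px: float, aspect: float) -> tuple[float, float]:
    """Principal sigmas of a 2D Gaussian whose half-maximum ellipse has the
    requested pixel area and axis ratio (area = 2π ln2 σx σy)."""
    s = area_px / (2.0 * math.pi * math.log(2.0))
    return math.sqrt(s * aspect), math.sqrt(s / aspect)


def _add_patch(target: np.ndarray, y0: int, x0: int, patch: np.ndarray) -> None:
    h, w = patch.shape
    target[y0 : y0 + h, x0 : x0 + w] += patch


def _gaussian_blob_3d(
    volume: np.ndarray, center: tuple[float, float, float],
    sigma_xy: float, sigma_z: float, amplitude: float,
) -> None:
    """Add an anisotropic 3D Gaussian at (x, y, z), in place, on a local patch."""
    x, y, z = center
    n_planes, H, W = volume.shape
    rxy = int(math.ceil(4 * sigma_xy))
    rz = int(math.ceil(4 * sigma_z))
    z0, z1 = max(0, int(z) - rz), min(n_planes, int(z) + rz + 1)
    y0, y1 = max(0, int(y) - rxy), min(H, int(y) + rxy + 1)
    x0, x1 = max(0, int(x) - rxy), min(W, int(x) + rxy + 1)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    g = amplitude * np.exp(
        -(((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma_xy**2) + (zz - z) ** 2 / (2 * sigma_z**2))
    )
    volume[z0:z1, y0:y1, x0:x1] += g.astype(volume.dtype)


def _footprint_patch(
    cell: GroundTruthCell, geometry: VoxelGeometry, shape: tuple[int, int], theta: float
) -> tuple[int, int, np.ndarray, np.ndarray]:
    """Return (y0, x0, gaussian_patch_normalized, local coords rotated) for the
    cell's cytoplasm footprint. The patch peaks at 1."""
    H, W = shape
    x, y, _ = cell.centroid_xyz
    area_px = cell.nominal_area / geometry.pixel_area_um2
    sx, sy = _footprint_sigmas(area_px, cell.aspect_ratio)
    r = int(math.ceil(3.2 * sx)) + 1
    y0, y1 = max(0, int(y) - r), min(H, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(W, int(x) + r + 1)
    yy, xx = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
    dx, dy = xx - x, yy - y
    u = dx * math.cos(theta) + dy * math.sin(theta)     # along major axis
    v = -dx * math.sin(theta) + dy * math.cos(theta)    # along minor axis
    g = np.exp(-(u**2 / (2 * sx**2) + v**2 / (2 * sy**2)))
    return y0, x0, g, np.stack([u, v])


def _render_actin(
    plane: np.ndarray, cell: GroundTruthCell, geometry: VoxelGeometry,
    shape: tuple[int, int], theta: float, rng: np.random.Generator,
) -> None:
    """Render the cell's actin pattern at its z-plane according to its
    texture class."""
    y0, x0, g, uv = _footprint_patch(cell, geometry, shape, theta)
    u, v = uv
    area_px = cell.nominal_area / geometry.pixel_area_um2
    sx, sy = _footprint_sigmas(area_px, cell.aspect_ratio)
    amp = cell.intensity_scale

    def spots(n: int, amplitude: float) -> np.ndarray:
        out = np.zeros_like(g)
        for _ in range(n):
            su = rng.normal(0.0, 0.55 * sx)
            sv = rng.normal(0.0, 0.55 * sy)
            d2 = (u - su) ** 2 + (v - sv) ** 2
            out += amplitude * np.exp(-d2 / (2 * 1.5**2))
        return out

    def ridges(n: int, amplitude: float) -> np.ndarray:
        out = np.zeros_like(g)
        half_len = 1.1 * sx * math.sqrt(_2LN2)
        for _ in range(n):
            off = rng.normal(0.0, 0.45 * sy)
            d = np.abs(v - off)
            mask = np.abs(u) < half_len
            out += amplitude * np.exp(-(d**2) / (2 * 1.2**2)) * mask
        return out

    cls = cell.texture_class
    if cls == "spot":
        patch = spots(max(4, int(area_px / 50)), 600.0 * amp)
    elif cls == "ridge":
        patch = ridges(3, 500.0 * amp)
    elif cls == "mixed":
        patch = spots(max(2, int(area_px / 100)), 300.0 * amp) + ridges(2, 250.0 * amp)
    else:  # flat
        patch = 300.0 * amp * (g > 0.5)
    h, w = patch.shape
    plane[y0 : y0 + h, x0 : x0 + w] += patch.astype(plane.dtype)


def generate_field_stack(
    truth_cells: Sequence[GroundTruthCell],
    geometry: VoxelGeometry,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    shape: tuple[int, int] = (512, 512),
) -> tuple[ImageStack, list[GroundTruthCell]]:
    """Rasterize one field of view from planted ground truth.

    Nuclei are 3D Gaussian blobs (σ_xy = 4 px, σ_z = 1 plane) at each
    centroid; the cytoplasm channel carries a 2D anisotropic Gaussian
    footprint at the cell's z-plane whose half-maximum ellipse matches
    ``nominal_area`` and ``aspect_ratio``; the actin channel is rendered per
    texture class (scattered peaks, oriented fibres, both, or a constant
    fill).  Additive Gaussian noise of ``noise_sd`` is applied to every
    channel (clipped at zero) and the ground truth is echoed back unchanged.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    H, W = shape
    n_planes = geometry.n_planes
    rng = np.random.default_rng(rng_seed)
    nuclei = np.zeros((n_planes, H, W), dtype=np.float32)
    cyto = np.zeros_like(nuclei)
    actin = np.zeros_like(nuclei)
    for cell in truth_cells:
        x, y, z = cell.centroid_xyz
        if not (0 <= x < W and 0 <= y < H and 0 <= z < n_planes):
            raise ValueError(f"cell centroid {cell.centroid_xyz} outside the field {shape} x {n_planes}")
        if cell.z_plane >= n_planes:
            raise ValueError(f"z_plane {cell.z_plane} outside the stack ({n_planes} planes)")
        theta = rng.uniform(0.0, math.pi)
        _gaussian_blob_3d(
            nuclei, (x, y, z), NUCLEUS_SIGMA_XY, NUCLEUS_SIGMA_Z,
            NUCLEUS_AMPLITUDE * cell.intensity_scale,
        )
        y0, x0, g, _ = _footprint_patch(cell, geometry, shape, theta)
        _add_patch(cyto[cell.z_plane], y0, x0, (CYTO_AMPLITUDE * cell.intensity_scale * g).astype(np.float32))
        _render_actin(actin[cell.z_plane], cell, geometry, shape, theta, rng)
    if noise_sd > 0:
        for arr in (nuclei, cyto, actin):
            arr += rng.normal(0.0, noise_sd, size=arr.shape).astype(np.float32)
            np.clip(arr, 0.0, None, out=arr)
    stack = ImageStack(
        channels={"nuclei": nuclei, "cytoplasm": cyto, "actin": actin},
        geometry=geometry,
    )
    return stack, list(truth_cells)


def _effect_for(layout: PlateLayout, well: str, effects: Mapping[str, EffectModel]) -> EffectModel:
    cond = layout.condition_label(well)
    if cond in effects:
        return effects[cond]
    row = layout.table.loc[layout.table["well"] == well].iloc[0]
    if row["role"] == "compound" and row["compound_id"] in effects:
        return effects[row["compound_id"]]
    raise KeyError(f"no EffectModel for condition {cond!r} (well {well})")


def generate_plate_dataset(
    spec: PlateSpec,
    effects: Mapping[str, EffectModel],
    geometry: VoxelGeometry,
    shape: tuple[int, int] = (512, 512),
    noise_sd: float = 20.0,
    field_fraction: float | None = None,
) -> tuple[dict[str, ImageStack], dict[str, list[GroundTruthCell]], PlateLayout]:
    """Render one field of view per well for a whole plate.

    Each well's cell count is drawn from its condition's whole-well count
    distribution and thinned to the field of view: the field holds a
    Binomial(n_well, field_area / well_area) subsample.  All draws come from a
    per-well substream keyed by (rng_seed, row, col), so identical inputs
    reproduce bit-identical outputs regardless of iteration order.
    """
    H, W = shape
    if field_fraction is None:
        field_um2 = (H * geometry.pixel_size_xy) * (W * geometry.pixel_size_xy)
        field_fraction = min(1.0, field_um2 / WELL_AREA_UM2)
    stacks: dict[str, ImageStack] = {}
    truths: dict[str, list[GroundTruthCell]] = {}
    for well in spec.layout.wells:
        effect = _effect_for(spec.layout, well, effects)
        rng = _well_rng(spec.rng_seed, well, stream=0)
        n_well = max(0, int(round(rng.normal(effect.n_cells_mean, effect.n_cells_sd))))
        n_field = int(rng.binomial(n_well, field_fraction)) if n_well else 0
        cells = sample_truth_cells(effect, n_field, geometry, shape, rng)
        render_seed = int(rng.integers(0, 2**31 - 1))
        stack, truth = generate_field_stack(
            cells, geometry, noise_sd=noise_sd, rng_seed=render_seed, shape=shape
        )
        stacks[well] = stack
        truths[well] = truth
    return stacks, truths, spec.layout


# ---------------------------------------------------------------------------
# aggregate (whole-well) layer


def sample_well_summaries(
    spec: PlateSpec,
    effects: Mapping[str, EffectModel],
    assessment_planes: Sequence[int] = (20, 40, 60, 80, 100),
) -> pd.DataFrame:
    """Draw whole-well summary statistics for a plate, without rendering.

    Returns one row per well with the quantities the screen's statistics
    consume: ``n_cells`` (= total nuclei), ``mean_area_um2``,
    ``mean_roundness``, ``migration_count`` (nuclei at the assessment
    depths).  Migrating cells are uniform over the migrating plane band, so
    the expected assessment count is ``n * migrated_fraction * k / band``
    with k assessment planes.
    """
    rows = []
    for _, lrow in spec.layout.table.iterrows():
        well = lrow["well"]
        effect = _effect_for(spec.layout, well, effects)
        rng = _well_rng(spec.rng_seed, well, stream=1)
        n = max(1, int(round(rng.normal(effect.n_cells_mean, effect.n_cells_sd))))
        well_area = 1.0 + rng.normal(0.0, effect.well_cv_area)
        well_round = 1.0 + rng.normal(0.0, effect.well_cv_roundness)
        mean_area = effect.area_um2_mean * well_area + rng.normal(0.0, effect.area_um2_sd / math.sqrt(n))
        mean_round = effect.roundness_mean * well_round + rng.normal(0.0, effect.roundness_sd / math.sqrt(n))
        mean_round = float(np.clip(mean_round, 1e-6, 1.0))
        migrated = int(rng.binomial(n, effect.migrated_fraction))
        lo, hi = effect.migration_planes
        band = hi - lo + 1
        k = sum(1 for p in assessment_planes if lo <= p <= hi)
        migration_count = int(rng.binomial(migrated, k / band)) if migrated else 0
        rows.append(
            {
                "well": well,
                "role": lrow["role"],
                "compound_id": lrow["compound_id"],
                "concentration_nM": lrow["concentration_nM"],
                "replicate": lrow["replicate"],
                "condition": spec.layout.condition_label(well),
                "n_cells": n,
                "mean_area_um2": float(mean_area),
                "mean_roundness": mean_round,
                "migration_count": migration_count,
                "total_nuclei": n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground-truth I/O

_TRUTH_COLUMNS = (
    "well", "x", "y", "z", "z_plane", "nominal_area_um2", "aspect_ratio",
    "texture_class", "intensity_scale",
)


def write_ground_truth(path: str | Path, truths: Mapping[str, Sequence[GroundTruthCell]]) -> Path:
    """Write planted cells as CSV, one row per cell."""
    rows = []
    for well, cells in truths.items():
        for c in cells:
            x, y, z = c.centroid_xyz
            rows.append(
                {
                    "well": well, "x": x, "y": y, "z": z, "z_plane": c.z_plane,
                    "nominal_area_um2": c.nominal_area, "aspect_ratio": c.aspect_ratio,
                    "texture_class": c.texture_class, "intensity_scale": c.intensity_scale,
                }
            )
    df = pd.DataFrame(rows, columns=list(_TRUTH_COLUMNS))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_ground_truth(path: str | Path) -> dict[str, list[GroundTruthCell]]:
    df = pd.read_csv(path)
    out: dict[str, list[GroundTruthCell]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["well"]), []).append(
            GroundTruthCell(
                centroid_xyz=(float(r["x"]), float(r["y"]), float(r["z"])),
                nominal_area=float(r["nominal_area_um2"]),
                aspect_ratio=float(r["aspect_ratio"]),
                z_plane=int(r["z_plane"]),
                texture_class=str(r["texture_class"]),
                intensity_scale=float(r["intensity_scale"]),
            )
        )
    return out
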