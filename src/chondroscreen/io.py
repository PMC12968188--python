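"""Image, plate-map and configuration I/O.

The on-disk layout is deliberately simple: one multi-page grayscale TIFF per
(well, channel) with pages in ascending z, a CSV plate map with one row per
well, and a YAML config for voxel geometry and pipeline thresholds.  Plane
index 0 is the gel floor (stacks are acquired from the bottom), so the depth
of plane ``i`` is ``i * z_step`` micrometres.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "VoxelGeometry",
    "ImageStack",
    "PlateLayout",
    "GeometryError",
    "PlateMapError",
    "morphology_geometry",
    "migration_geometry",
    "read_stack",
    "write_stack",
    "read_plate_map",
    "write_plate_map",
    "read_geometry_config",
    "write_geometry_config",
]

CHANNEL_NAMES = ("nuclei", "cytoplasm", "actin")

#: column order for plate-map CSVs
PLATE_MAP_COLUMNS = ("well", "role", "compound_id", "concentration_nM", "replicate")

ROLES = ("negative", "positive", "compound")


class GeometryError(ValueError):
    """Stack dimensions are inconsistent with the declared voxel geometry."""


class PlateMapError(ValueError):
    """Plate-map table violates the screen's layout contract."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Acquisition geometry of a confocal z-stack.

    Parameters
    ----------
    pixel_size_xy : float
        Lateral calibration in µm per pixel. There is no default: it must be
        supplied from the instrument's metadata or a config file.
    z_step : float
        Axial spacing between optical sections, µm.
    n_planes : int
        Number of optical sections in the stack.
    objective_label : str
        Free-text objective description, carried through to outputs.
    """

    pixel_size_xy: float
    z_step: float
    n_planes: int
    objective_label: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_xy <= 0 or self.z_step <= 0 or self.n_planes <= 0:
            raise GeometryError(
                "pixel_size_xy, z_step and n_planes must all be strictly positive"
            )

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_xy**2

    def plane_depth_um(self, plane_index: int) -> float:
        """Depth of a plane below the gel floor (plane 0), in µm."""
        if plane_index < 0:
            raise ValueError("plane index must be non-negative")
        return plane_index * self.z_step


def morphology_geometry(pixel_size_xy: float, objective_label: str = "40x water NA 1.1") -> VoxelGeometry:
    """Geometry of the morphology acquisition setup: 8 planes at 2 µm steps."""
    return VoxelGeometry(pixel_size_xy, z_step=2.0, n_planes=8, objective_label=objective_label)


def migration_geometry(pixel_size_xy: float, objective_label: str = "20x water NA 1.0") -> VoxelGeometry:
    """Geometry of the migration acquisition setup: 102 planes at 5 µm steps,
    spanning the ~500 µm of gel above the floor."""
    return VoxelGeometry(pixel_size_xy, z_step=5.0, n_planes=102, objective_label=objective_label)


@dataclass
class ImageStack:
    """A multi-channel 3D image: channel name -> (planes, rows, cols) array."""

    channels: dict[str, np.ndarray]
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        shapes = {c: a.shape for c, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise GeometryError(f"channels differ in shape: {shapes}")
        if len(first) != 3:
            raise GeometryError("channel arrays must be 3D (planes, rows, cols)")
        if first[0] != self.geometry.n_planes:
            raise GeometryError(
                f"stack has {first[0]} planes but geometry declares {self.geometry.n_planes}"
            )
        for name, arr in self.channels.items():
            if np.min(arr) < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"channel {name!r} not present (have {sorted(self.channels)})") from None


_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A1'-style well address."""
    return f"{chr(ord('A') + row)}{col + 1}"


def well_address(name: str) -> tuple[int, int]:
    """'A1'-style well address -> 0-based (row, col)."""
    m = _WELL_RE.match(name.strip())
    if not m or int(m.group(2)) < 1:
        raise PlateMapError(f"malformed well address {name!r}")
    return ord(m.group(1)) - ord("A"), int(m.group(2)) - 1


@dataclass
class PlateLayout:
    """Well -> experimental condition assignment for one plate.

    ``table`` has one row per well with columns ``well, role, compound_id,
    concentration_nM, replicate``.  Control wells carry null compound fields;
    compound wells must name a compound and a concentration.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PLATE_MAP_COLUMNS if c not in t.columns]
        if missing:
            raise PlateMapError(f"plate map missing columns: {missing}")
        if len(t) == 0:
            raise PlateMapError("plate map is empty")
        if t["well"].duplicated().any():
            dups = sorted(t.loc[t["well"].duplicated(), "well"])
            raise PlateMapError(f"duplicate well addresses: {dups}")
        for w in t["well"]:
            well_address(str(w))
        bad_roles = set(t["role"]) - set(ROLES)
        if bad_roles:
            raise PlateMapError(f"unknown roles: {sorted(bad_roles)}")
        comp = t[t["role"] == "compound"]
        if comp["compound_id"].isna().any() or (comp["compound_id"] == "").any():
            raise PlateMapError("compound wells must have a compound_id")
        if comp["concentration_nM"].isna().any():
            raise PlateMapError("compound wells must have a concentration_nM")
        ctrl = t[t["role"] != "compound"]
        if ctrl["compound_id"].notna().any() or ctrl["concentration_nM"].notna().any():
            raise PlateMapError("control wells must have null compound fields")
        self.table = t.reset_index(drop=True)

    @property
    def wells(self) -> list[str]:
        return list(self.table["well"])

    def wells_with_role(self, role: str) -> list[str]:
        return list(self.table.loc[self.table["role"] == role, "well"])

    def condition_label(self, well: str) -> str:
        """Human-readable condition key: 'negative', 'positive' or
        '<compound>@<conc>nM'."""
        row = self.table.loc[self.table["well"] == well]
        if len(row) != 1:
            raise KeyError(f"well {well!r} not in layout")
        row = row.iloc[0]
        if row["role"] == "compound":
            return f"{row['compound_id']}@{row['concentration_nM']:g}nM"
        return "negative" if row["role"] == "negative" else "positive"


def write_stack(path: str | Path, stack_or_array: ImageStack | np.ndarray, channel: str | None = None) -> Path:
    """Write one channel as a multi-page TIFF, one page per z-plane.

    Accepts either a bare 3D array or an :class:`ImageStack` plus a channel
    name.  Values are written as-is (dtype preserved), so the round trip is
    lossless.
    """
    path = Path(path)
    if isinstance(stack_or_array, ImageStack):
        if channel is None:
            raise ValueError("channel name required when writing from an ImageStack")
        data = stack_or_array.channel(channel)
    else:
        data = np.asarray(stack_or_array)
        if data.ndim != 3:
            raise GeometryError("expected a 3D (planes, rows, cols) array")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def read_stack(
    paths: Mapping[str, str | Path] | str | Path,
    geometry: VoxelGeometry,
) -> ImageStack:
    """Read per-channel multi-page TIFFs into an :class:`ImageStack`.

    Parameters
    ----------
    paths : mapping or path
        Either ``{channel_name: tiff_path}`` or a single path, in which case
        the channel is called ``"nuclei"``.
    geometry : VoxelGeometry
        Declared acquisition geometry; a page-count mismatch raises
        :class:`GeometryError` rather than being silently accepted.
    """
    if not isinstance(paths, Mapping):
        paths = {"nuclei": paths}
    channels: dict[str, np.ndarray] = {}
    for name, p in paths.items():
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.shape[0] != geometry.n_planes:
            raise GeometryError(
                f"{p.name}: {arr.shape[0]} pages but geometry declares "
                f"{geometry.n_planes} planes"
            )
        channels[name] = arr
    return ImageStack(channels=channels, geometry=geometry)


def write_plate_map(path: str | Path, layout: PlateLayout) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    layout.table.loc[:, PLATE_MAP_COLUMNS].to_csv(path, index=False, float_format="%.6g")
    return path


def read_plate_map(path: str | Path) -> PlateLayout:
    """Read and validate a plate-map CSV (columns: well, role, compound_id,
    concentration_nM, replicate)."""
    path = Path(path)
    try:
        t = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise PlateMapError(f"{path}: empty plate map") from None
    if "compound_id" in t.columns:
        t["compound_id"] = t["compound_id"].astype("object").where(t["compound_id"].notna(), None)
    return PlateLayout(table=t)


def write_geometry_config(path: str | Path, geometry: VoxelGeometry, extra: dict | None = None) -> Path:
    path = Path(path)
    payload = {
        "pixel_size_xy_um": float(geometry.pixel_size_xy),
        "z_step_um": float(geometry.z_step),
        "n_planes": int(geometry.n_planes),
        "objective_label": geometry.objective_label,
    }
    if extra:
        payload.update(extra)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_geometry_config(path: str | Path) -> VoxelGeometry:
    cfg = yaml.safe_load(Path(path).read_text())
    try:
        return VoxelGeometry(
            pixel_size_xy=float(cfg["pixel_size_xy_um"]),
            z_step=float(cfg["z_step_um"]),
            n_planes=int(cfg["n_planes"]),
            objective_label=str(cfg.get("objective_label", "")),
        )
    except KeyError as e:
        raise GeometryError(f"geometry config missing key {e}") from None
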