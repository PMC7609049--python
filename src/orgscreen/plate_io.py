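"""Plate, well and image-stack data model plus TIFF/CSV/YAML I/O.

The pipeline operates on calibrated multi-channel confocal z-stacks, one
or more tiled fields of view per well of a microtiter plate.  Intensities
are kept in the imager's arbitrary brightness units (abu); all physical
quantities carry explicit µm calibration so that object areas can be
reported in µm² while the algorithms operate on pixels.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

CHANNEL_ROLES = frozenset(
    {"nuclear", "nuclear-marker", "filamentous", "cytoplasmic", "brightfield"}
)


@dataclass(frozen=True)
class ChannelSpec:
    """A named imaging channel with its biological role.

    ``role`` selects the quantification route downstream: nuclear(-marker)
    channels are segmented into objects, filamentous channels are measured
    as mean intensity within the aggregate region.
    """

    name: str
    role: str = "nuclear-marker"

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise ValueError(
                f"unknown channel role {self.role!r}; expected one of {sorted(CHANNEL_ROLES)}"
            )


@dataclass
class ImageStack:
    """A calibrated (channel, plane, row, column) intensity grid.

    All intensities are non-negative abu.  ``pixel_size_um`` is the lateral
    calibration; ``plane_spacing_um`` the distance between plane centers.
    """

    voxels: np.ndarray
    pixel_size_um: float
    plane_spacing_um: float
    channels: Sequence[ChannelSpec]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be 4-D (channel, plane, row, column)")
        if self.pixel_size_um <= 0 or self.plane_spacing_um <= 0:
            raise ValueError("calibration values must be positive")
        if len(self.channels) != self.voxels.shape[0]:
            raise ValueError(
                f"channel count {len(self.channels)} does not match first-axis "
                f"extent {self.voxels.shape[0]}"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique within a stack")
        if self.voxels.size and float(self.voxels.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def channel_names(self) -> list:
        return [c.name for c in self.channels]

    @property
    def axial_span_um(self) -> float:
        """Distance between the first and last plane centers.

        A 16-plane stack at 36.6 µm spacing spans 15 x 36.6 = 549 µm.
        """
        return (self.n_planes - 1) * self.plane_spacing_um

    def channel(self, name: str) -> np.ndarray:
        """Return the (plane, row, column) grid of one channel by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.voxels[idx]

    def area_um2(self, n_pixels: int | float) -> float:
        """Convert a pixel count to µm² using the lateral calibration."""
        return float(n_pixels) * self.pixel_size_um**2


@dataclass
class PlateLayout:
    """Microtiter plate geometry and per-well annotations (96-well default)."""

    rows: int = 8
    columns: int = 12
    well_annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for well in self.well_annotations:
            self.parse_well_id(well)

    def parse_well_id(self, well_id: str) -> tuple:
        """Split e.g. 'A1' into 0-based (row, column); raise on invalid ids."""
        if not well_id or not well_id[0].isalpha():
            raise ValueError(f"invalid well id {well_id!r}")
        row = string.ascii_uppercase.index(well_id[0].upper())
        try:
            col = int(well_id[1:]) - 1
        except ValueError:
            raise ValueError(f"invalid well id {well_id!r}")
        if not (0 <= row < self.rows and 0 <= col < self.columns):
            raise ValueError(f"well id {well_id!r} outside {self.rows}x{self.columns} plate")
        return row, col

    def well_ids(self) -> list:
        return [
            f"{string.ascii_uppercase[r]}{c + 1}"
            for r in range(self.rows)
            for c in range(self.columns)
        ]


@dataclass
class WellImageSet:
    """All image data of one well: tiled non-overlapping fields + brightfield."""

    well_id: str
    fields_of_view: Sequence[ImageStack]
    brightfield: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.fields_of_view:
            raise ValueError("a well needs at least one field of view")
        first = self.fields_of_view[0]
        for fov in self.fields_of_view[1:]:
            if (
                fov.pixel_size_um != first.pixel_size_um
                or fov.plane_spacing_um != first.plane_spacing_um
                or fov.channel_names != first.channel_names
            ):
                raise ValueError("all fields of a well must share calibration and channels")

    @property
    def channel_names(self) -> list:
        return self.fields_of_view[0].channel_names


def classify_well_position(well_id: str, layout: PlateLayout) -> str:
    """Classify a well as ``"edge"`` (outermost ring) or ``"inside"``.

    Edge wells often display systematically different readouts than wells
    toward the plate center, so per-well summaries carry this class.  On a
    96-well plate exactly 36 wells are edge and 60 inside.
    """
    row, col = layout.parse_well_id(well_id)
    if row in (0, layout.rows - 1) or col in (0, layout.columns - 1):
        return "edge"
    return "inside"


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an ImageStack as a multi-page TIFF (plane-major pages per channel).

    Calibration is stored in the TIFF description so that
    :func:`read_stack` can round-trip it without a side-car config.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "axes": "CZYX",
        "pixel_size_um": stack.pixel_size_um,
        "plane_spacing_um": stack.plane_spacing_um,
        "channels": [{"name": c.name, "role": c.role} for c in stack.channels],
    }
    tifffile.imwrite(path, stack.voxels, metadata=meta)
    return path


def read_stack(
    path: str | Path,
    calibration: Mapping | None = None,
    channels: Sequence[ChannelSpec] | None = None,
    n_planes: int | None = None,
) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack` (or compatible).

    ``calibration`` ({pixel_size_um, plane_spacing_um}) and ``channels``
    override anything found in the file metadata; at least one source must
    provide them.  ``n_planes`` asserts the expected plane count.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if channels is None:
        if "channels" not in meta:
            raise ValueError(f"{path}: channel list neither in metadata nor declared")
        channels = [ChannelSpec(c["name"], c["role"]) for c in meta["channels"]]
    if voxels.ndim == 3:
        # single channel written without a channel axis
        voxels = voxels[None] if len(channels) == 1 else voxels[:, None]
    if calibration is None:
        calibration = meta
    try:
        pixel_size = float(calibration["pixel_size_um"])
        spacing = float(calibration["plane_spacing_um"])
    except KeyError as exc:
        raise ValueError(f"{path}: calibration value missing: {exc}")
    stack = ImageStack(voxels, pixel_size, spacing, list(channels))
    if n_planes is not None and stack.n_planes != n_planes:
        raise ValueError(
            f"{path}: config declares {n_planes} planes but file holds {stack.n_planes}"
        )
    return stack


# --- result tables -------------------------------------------------------

#: column order of the per-well result table; one row per well x marker
RESULT_COLUMNS = [
    "well_id",
    "marker",
    "n_objects",
    "total_brightness_abu",
    "aggregate_area_um2",
    "filament_intensity_abu",
    "qc_pass",
    "position_class",
]


def write_results(records: Iterable, path: str | Path) -> Path:
    """Write per-well summaries as a tidy CSV, one row per well x marker.

    Accepts any iterable of objects exposing the RESULT_COLUMNS as
    attributes or mapping keys.  An empty record set produces a file with
    the header only.  Values round-trip exactly through read_results.
    """
    rows = []
    for rec in records:
        if isinstance(rec, Mapping):
            rows.append({k: rec.get(k) for k in RESULT_COLUMNS})
        else:
            rows.append({k: getattr(rec, k, None) for k in RESULT_COLUMNS})
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- run configuration ---------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration and apply schema defaults.

    Recognised top-level keys: calibration, channels, gates, detection,
    background, layout, seed, output_dir.  Unknown keys are rejected so
    typos fail before any processing starts.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {
        "calibration",
        "channels",
        "gates",
        "detection",
        "background",
        "layout",
        "qc",
        "seed",
        "output_dir",
        "paths",
    }
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    config = {"seed": 0, "layout": {"rows": 8, "columns": 12}}
    config.update(raw)
    return config
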