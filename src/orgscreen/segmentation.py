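"""Stage 3: nucleus / cell detection inside the aggregate and gating.

Objects are seeded at local intensity maxima of the background-corrected
plane at the expected object scale and grown by marker-controlled
watershed; this stands in for the proprietary "find nuclei" / "find
cells" routines of commercial HCS software, with equivalence claimed at
the level of gated counts on well-separated objects, not pixel masks.

Brightness is measured on the RAW channel (the corrected image is used
for detection only) and reported both as the SUM over the object
footprint — the quantity summed per well downstream — and as the mean.
Accept/reject windows on area (µm²) and brightness (abu) implement the
strict "larger than / brighter than" semantics: an object passes a
minimum bound strictly (>) and fails a maximum bound strictly (>), so
values equal to a cap are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed


@dataclass
class SegmentedObject:
    """One segmented nucleus or cell on a single plane."""

    plane_index: int
    centroid: tuple
    area_um2: float
    total_brightness_abu: float
    mean_brightness_abu: float
    marker: str = ""
    accepted: bool = True
    rejection_reason: str | None = None


@dataclass(frozen=True)
class GateSpec:
    """Accept/reject window on object area and brightness.

    Reference windows from the worked analyses: Sox2 nuclei 10-70 µm² /
    1200-6000 abu; TH and Map2 cells min 25 µm² / 200 abu; cCasp3 nuclei
    11-100 µm² / min 2700 abu.
    """

    min_area_um2: float = 0.0
    max_area_um2: float | None = None
    min_brightness_abu: float = 0.0
    max_brightness_abu: float | None = None

    def __post_init__(self) -> None:
        if self.max_area_um2 is not None and self.max_area_um2 <= self.min_area_um2:
            raise ValueError("max_area_um2 must exceed min_area_um2")
        if (
            self.max_brightness_abu is not None
            and self.max_brightness_abu <= self.min_brightness_abu
        ):
            raise ValueError("max_brightness_abu must exceed min_brightness_abu")


#: Gate windows from the reference analyses, keyed by marker.
PAPER_GATES = {
    "Sox2": GateSpec(10.0, 70.0, 1200.0, 6000.0),
    "TH": GateSpec(min_area_um2=25.0, min_brightness_abu=200.0),
    "Map2": GateSpec(min_area_um2=25.0, min_brightness_abu=200.0),
    "cCasp3": GateSpec(11.0, 100.0, 2700.0),
}


@dataclass(frozen=True)
class SegmentationParams:
    """Scale and sensitivity of the object finder.

    ``expected_diameter_um`` sets the smoothing scale and the minimum
    seed separation; ``detection_threshold`` (abu, on the smoothed
    corrected image) sets seed sensitivity.  ``grow_threshold_fraction``
    bounds watershed growth at that fraction of the seed threshold.
    """

    expected_diameter_um: float = 7.0
    detection_threshold: float = 75.0
    grow_threshold_fraction: float = 0.5
    min_area_px: int = 4


#: defaults tuned for soma-scale objects (larger, dimmer after high-pass)
CELL_PARAMS = SegmentationParams(expected_diameter_um=12.0, detection_threshold=40.0)


def _segment(
    corrected: np.ndarray,
    raw: np.ndarray,
    mask: np.ndarray | None,
    pixel_size_um: float,
    params: SegmentationParams,
    plane_index: int,
    marker: str,
) -> list:
    corrected = np.asarray(corrected, dtype=np.float64)
    raw = np.asarray(raw, dtype=np.float64)
    d_px = params.expected_diameter_um / pixel_size_um
    sigma = max(0.8, 0.25 * d_px)
    smoothed = ndimage.gaussian_filter(corrected, sigma)
    region = np.ones(corrected.shape, dtype=bool) if mask is None else mask.astype(bool)
    grow = smoothed > params.grow_threshold_fraction * params.detection_threshold
    grow &= region
    seeds = peak_local_max(
        smoothed,
        min_distance=max(1, int(round(0.35 * d_px))),
        threshold_abs=params.detection_threshold,
        exclude_border=False,
    )
    # keep seeds inside the aggregate region; ties in flooding are broken
    # by marker id, itself assigned in (row, col) order for determinism
    seeds = [tuple(s) for s in seeds if region[tuple(s)]]
    if not seeds:
        return []
    markers = np.zeros(corrected.shape, dtype=np.int32)
    for i, (r, c) in enumerate(sorted(seeds), start=1):
        markers[r, c] = i
    labels = watershed(-smoothed, markers=markers, mask=grow)
    objects = []
    for prop in regionprops(labels, intensity_image=raw):
        if prop.area < params.min_area_px:
            continue
        footprint = labels == prop.label
        total = float(raw[footprint].sum())
        objects.append(
            SegmentedObject(
                plane_index=plane_index,
                centroid=tuple(prop.centroid),
                area_um2=float(prop.area) * pixel_size_um**2,
                total_brightness_abu=total,
                mean_brightness_abu=total / prop.area,
                marker=marker,
            )
        )
    objects.sort(key=lambda o: o.centroid)
    return objects


def find_nuclei(
    corrected_plane: np.ndarray,
    raw_plane: np.ndarray,
    mask: np.ndarray | None,
    pixel_size_um: float,
    params: SegmentationParams = SegmentationParams(),
    plane_index: int = 0,
    marker: str = "",
) -> list:
    """Detect nucleus-scale objects within the aggregate region.

    Detection runs on the background-corrected plane; brightness is
    measured on the raw plane.  Objects are clipped to ``mask`` (seeds
    outside it are discarded).  An empty result is valid.
    """
    return _segment(corrected_plane, raw_plane, mask, pixel_size_um, params, plane_index, marker)


def find_cells(
    corrected_plane: np.ndarray,
    raw_plane: np.ndarray,
    mask: np.ndarray | None,
    pixel_size_um: float,
    params: SegmentationParams = CELL_PARAMS,
    plane_index: int = 0,
    marker: str = "",
) -> list:
    """As :func:`find_nuclei`, tuned for larger soma-scale objects."""
    return _segment(corrected_plane, raw_plane, mask, pixel_size_um, params, plane_index, marker)


def apply_gate(objects: Sequence[SegmentedObject], gate: GateSpec) -> list:
    """Set accept flags on measured objects; order preserved, idempotent.

    Checks run in the order too_small, too_large, too_dim, too_bright and
    the first failure is recorded.
    """
    out = []
    for obj in objects:
        reason = None
        if not obj.area_um2 > gate.min_area_um2:
            reason = "too_small"
        elif gate.max_area_um2 is not None and obj.area_um2 > gate.max_area_um2:
            reason = "too_large"
        elif not obj.total_brightness_abu > gate.min_brightness_abu:
            reason = "too_dim"
        elif (
            gate.max_brightness_abu is not None
            and obj.total_brightness_abu > gate.max_brightness_abu
        ):
            reason = "too_bright"
        out.append(replace(obj, accepted=reason is None, rejection_reason=reason))
    return out


def classify_double_positive(
    objects_a: Sequence[SegmentedObject],
    objects_b: Sequence[SegmentedObject],
    max_center_distance_um: float,
    pixel_size_um: float = 1.0,
) -> list:
    """Match accepted objects across two channels of the same plane.

    Greedy nearest-neighbour matching under the distance cap: candidate
    pairs are sorted by centroid distance and consumed closest-first,
    each object matched at most once.  A matched pair marks a cell as
    double-positive (it satisfies both channel filters at once).
    """
    acc_a = [o for o in objects_a if o.accepted]
    acc_b = [o for o in objects_b if o.accepted]
    if not acc_a or not acc_b:
        return []
    ca = np.array([o.centroid for o in acc_a], dtype=float) * pixel_size_um
    cb = np.array([o.centroid for o in acc_b], dtype=float) * pixel_size_um
    dists = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    candidates = [
        (dists[i, j], i, j)
        for i in range(len(acc_a))
        for j in range(len(acc_b))
        if dists[i, j] <= max_center_distance_um
    ]
    candidates.sort()
    used_a: set = set()
    used_b: set = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((acc_a[i], acc_b[j]))
    return pairs
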