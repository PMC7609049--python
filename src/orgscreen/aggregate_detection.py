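"""Stage 1: find the organoid region on each confocal plane; flag bad wells.

One aggregate is expected per well.  On each plane the channels are
summed, smoothed, thresholded, and the boundary cleaned by dilation and
erosion (defaults 10 and 3 px — the asymmetric pair is kept verbatim, so
the mask grows by ~7 px).  Candidate regions must exceed a minimum size
(default 4000 µm²) and a minimum mean brightness (default 300 abu) to
count as bona fide aggregates; anything else is dust, fibers or noise.

QC rejects wells containing dust in the organoid's field of view,
fibers, incompletely imaged aggregates (mask touching the image border),
damaged aggregates, or no aggregate at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, erosion

from .plate_io import ChannelSpec, ImageStack, WellImageSet


@dataclass
class RegionMask:
    """One detected aggregate region on a single confocal plane.

    ``mask`` is the boundary-cleaned region (after the asymmetric
    dilate/erode, so grown by ~7 px with the default 10/3 pair) used to
    clip downstream segmentation; ``area_um2`` and
    ``mean_brightness_abu`` are measured on the raw thresholded
    foreground within the region, so the size/brightness gates see the
    actual sample footprint rather than the grown envelope.
    """

    plane_index: int
    mask: np.ndarray
    area_um2: float
    mean_brightness_abu: float
    roundness: float  # 4*pi*area / perimeter^2, in (0, 1]
    sample_mask: np.ndarray | None = None  # raw thresholded foreground

    @property
    def touches_border(self) -> bool:
        m = self.mask
        return bool(m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any())


@dataclass(frozen=True)
class DetectionParams:
    """Aggregate-identification parameters; defaults are the reference
    analysis values for full-size organoids (4000 µm², 300 abu mean).

    ``threshold_method`` is "otsu" (on the smoothed summed plane) or
    "absolute" with ``threshold_value`` in abu.  The minimum-brightness
    gate applies to the region MEAN intensity by default; set
    ``brightness_statistic="total"`` to gate on the integrated sum.
    """

    smooth_method: str = "median"
    smooth_width_px: int = 5
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    dilate_px: int = 10
    erode_px: int = 3
    min_area_um2: float = 4000.0
    min_brightness_abu: float = 300.0
    brightness_statistic: str = "mean"


@dataclass
class QCVerdict:
    """Per-well quality-control outcome; pass implies no reasons."""

    well_id: str
    qc_pass: bool
    reasons: set = field(default_factory=set)


@dataclass(frozen=True)
class ArtifactParams:
    """Thresholds for recognising dust and fibers during QC."""

    dust_min_area_um2: float = 4.0
    dust_min_brightness_abu: float = 600.0
    fiber_roundness_max: float = 0.2
    fiber_min_um: float = 50.0


def sum_channels(stack: ImageStack, channels: Sequence[str] | None = None) -> ImageStack:
    """Sum a subset of channels into a single-channel stack (float64).

    Summing widens the intensity range, so the result is saturation-free
    even when individual channels were near their bit depth.
    """
    names = stack.channel_names if channels is None else list(channels)
    if not names:
        raise ValueError("channel subset must be non-empty")
    summed = np.zeros(stack.voxels.shape[1:], dtype=np.float64)
    for name in names:
        summed += stack.channel(name)
    return ImageStack(
        summed[None],
        stack.pixel_size_um,
        stack.plane_spacing_um,
        [ChannelSpec("sum", "nuclear")],
    )


def _smooth(plane: np.ndarray, params: DetectionParams) -> np.ndarray:
    f = np.asarray(plane, dtype=np.float64)
    if params.smooth_method == "median":
        return ndimage.median_filter(f, size=params.smooth_width_px)
    if params.smooth_method == "gaussian":
        return ndimage.gaussian_filter(f, params.smooth_width_px)
    raise ValueError(f"unknown smoothing method {params.smooth_method!r}")


def _threshold(smoothed: np.ndarray, params: DetectionParams) -> np.ndarray | None:
    if params.threshold_method == "absolute":
        if params.threshold_value is None:
            raise ValueError("absolute thresholding needs threshold_value")
        return smoothed > params.threshold_value
    if params.threshold_method == "otsu":
        if smoothed.max() - smoothed.min() < 1e-9:
            return None
        return smoothed > threshold_otsu(smoothed)
    raise ValueError(f"unknown threshold method {params.threshold_method!r}")


def _measure_region(
    mask: np.ndarray, raw: np.ndarray, pixel_size_um: float, plane_index: int
) -> RegionMask:
    props = regionprops(mask.astype(np.uint8), intensity_image=raw)[0]
    perim = max(props.perimeter, 1e-9)
    roundness = min(1.0, 4.0 * np.pi * props.area / perim**2)
    return RegionMask(
        plane_index=plane_index,
        mask=mask,
        area_um2=float(props.area) * pixel_size_um**2,
        mean_brightness_abu=float(props.intensity_mean),
        roundness=roundness,
    )


def detect_aggregate(
    plane: np.ndarray,
    pixel_size_um: float,
    params: DetectionParams = DetectionParams(),
    plane_index: int = 0,
) -> list:
    """Detect bona fide aggregate regions on one (summed-channel) plane.

    Returns the regions that survive smoothing, thresholding, boundary
    cleaning and the size/brightness gates, largest first.  An empty list
    is a valid outcome: the plane may lie above or below the organoid.
    """
    raw = np.asarray(plane, dtype=np.float64)
    smoothed = _smooth(raw, params)
    raw_fg = _threshold(smoothed, params)
    if raw_fg is None or not raw_fg.any():
        return []
    cleaned = raw_fg
    if params.dilate_px > 0:
        cleaned = dilation(cleaned, disk(params.dilate_px))
    if params.erode_px > 0:
        cleaned = erosion(cleaned, disk(params.erode_px))
    if not cleaned.any():
        return []
    labels = cc_label(cleaned)
    regions = []
    for lbl in range(1, labels.max() + 1):
        mask = labels == lbl
        sample = mask & raw_fg
        n_px = int(sample.sum())
        if n_px == 0:
            continue
        area_um2 = n_px * pixel_size_um**2
        if area_um2 < params.min_area_um2:
            continue
        mean_brightness = float(raw[sample].mean())
        brightness = mean_brightness * n_px if params.brightness_statistic == "total" else mean_brightness
        if brightness < params.min_brightness_abu:
            continue
        props = regionprops(sample.astype(np.uint8))[0]
        roundness = min(1.0, 4.0 * np.pi * props.area / max(props.perimeter, 1e-9) ** 2)
        regions.append(
            RegionMask(plane_index, mask, area_um2, mean_brightness, roundness, sample)
        )
    regions.sort(key=lambda r: r.area_um2, reverse=True)
    return regions


def _off_aggregate_objects(
    plane: np.ndarray,
    aggregate_mask: np.ndarray | None,
    pixel_size_um: float,
    params: DetectionParams,
) -> list:
    """Thresholded connected components that do not belong to the aggregate."""
    raw = np.asarray(plane, dtype=np.float64)
    binary = _threshold(_smooth(raw, params), params)
    if binary is None:
        return []
    if aggregate_mask is not None:
        # the aggregate mask was grown by dilate/erode; pad a little more
        grown = dilation(aggregate_mask, disk(3))
        binary = binary & ~grown
    labels = cc_label(binary)
    out = []
    for prop in regionprops(labels, intensity_image=raw):
        mask = labels == prop.label
        out.append(_measure_region(mask, raw, pixel_size_um, 0))
    return out


def qc_classify(
    well: WellImageSet,
    regions_per_plane: dict,
    artifact_params: ArtifactParams = ArtifactParams(),
    detection_params: DetectionParams = DetectionParams(),
) -> QCVerdict:
    """Classify a well as usable or rejected, with reasons.

    ``regions_per_plane`` maps (fov_index, plane_index) -> list of
    RegionMask from :func:`detect_aggregate`.  Reasons: ``dust`` (compact
    bright off-aggregate object), ``fiber`` (elongated bright streak),
    ``incomplete`` (aggregate touching the image border on any plane),
    ``missing`` (no aggregate found on any plane).
    """
    reasons: set = set()
    any_region = False
    for fov_idx, fov in enumerate(well.fields_of_view):
        summed = sum_channels(fov).voxels[0]
        for plane_idx in range(fov.n_planes):
            regions = regions_per_plane.get((fov_idx, plane_idx), [])
            agg = regions[0] if regions else None
            if agg is not None:
                any_region = True
                if agg.touches_border:
                    reasons.add("incomplete")
            for obj in _off_aggregate_objects(
                summed[plane_idx],
                agg.mask if agg is not None else None,
                fov.pixel_size_um,
                detection_params,
            ):
                if (
                    obj.roundness < artifact_params.fiber_roundness_max
                    and obj.area_um2 >= artifact_params.dust_min_area_um2
                ):
                    # elongated: estimate length from the bounding footprint
                    rows, cols = np.nonzero(obj.mask)
                    extent = max(np.ptp(rows), np.ptp(cols)) * fov.pixel_size_um
                    if extent > artifact_params.fiber_min_um:
                        reasons.add("fiber")
                        continue
                if (
                    obj.area_um2 >= artifact_params.dust_min_area_um2
                    and obj.mean_brightness_abu > artifact_params.dust_min_brightness_abu
                ):
                    reasons.add("dust")
    if not any_region:
        reasons.add("missing")
    return QCVerdict(well_id=well.well_id, qc_pass=not reasons, reasons=reasons)
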