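"""Synthetic 3D organoid stacks, plates and time-series with ground truth.

No public image data exists for this kind of whole-mount-stained,
BABB-cleared organoid screen, so every analysis stage is exercised on
simulated data instead.  The generator emulates the features that drive
the analysis design, at a configurable scale:

* roughly spherical aggregates with nuclei placed by dart throwing
  (minimum center distance 1.5x the nucleus radius by default, so blobs
  are resolvable; the factor can be lowered to stress-test segmentation
  with overlapping nuclei);
* concentric marker zones (precursor markers enriched in the core);
* nuclear blob signals — each nucleus is rendered exactly once, as a 2-D
  Gaussian on its nearest confocal plane, idealising one optical section
  per plane slab; per-plane counts therefore follow the
  circle-of-latitude profile of the sphere and sum to the planted total;
* filamentous textures as oriented random chords within the aggregate;
* depth-dependent exponential attenuation and a smooth additive haze
  (the residual non-uniform background of large cleared samples);
* dilution-series tracker labelling with binomial realisation;
* dust / fiber artifacts as QC positive controls;
* toxin-driven ablation of marker-specific subpopulations;
* periodic synchronized calcium spikes and two-tone field potentials.

It does not model light scattering, a realistic PSF, or optical
cross-talk; see the methods note for what that implies for the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line as draw_line

from .plate_io import ChannelSpec, ImageStack, PlateLayout, classify_well_position
from .timeseries import TraceSet

TRACKER = "Tracker"


@dataclass
class OrganoidPhenotype:
    """What the simulated organoid looks like.

    ``zone_fractions`` maps a nuclear marker to per-zone positive
    fractions, core first (three equal-width concentric shells by
    default).  ``filament_density`` maps a filamentous marker to its mean
    in-mask intensity in abu.  ``labeled_fraction``, if set, adds a
    tracker-dye channel where each nucleus is labelled independently
    with that probability (dilution-series model).
    """

    radius_um: float = 200.0
    n_nuclei: int = 2000
    zone_fractions: dict = field(default_factory=lambda: {"Sox2": (0.8, 0.45, 0.15)})
    nucleus_radius_um: tuple = (3.5, 0.5)
    filament_density: dict = field(default_factory=dict)
    labeled_fraction: float | None = None
    marker_radius_um: dict = field(default_factory=dict)
    min_separation_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.radius_um <= self.nucleus_radius_um[0]:
            raise ValueError("aggregate radius must exceed the nucleus radius")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        for marker, fracs in self.zone_fractions.items():
            if any(not 0 <= f <= 1 for f in np.atleast_1d(fracs)):
                raise ValueError(f"zone fractions for {marker} must lie in [0, 1]")
        if self.labeled_fraction is not None and not 0 <= self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must lie in [0, 1]")


@dataclass
class AcquisitionModel:
    """Optical imperfections of the simulated imager.

    ``attenuation_per_um`` — exponential intensity decay with depth from
    the top plane (residual absorption/scatter after clearing).
    ``haze_amplitude`` / ``haze_scale_um`` — smooth additive background
    following the sample's thickness profile plus a random smooth field.
    ``abu_per_fluorophore`` — gain: peak abu of one nucleus blob.
    """

    attenuation_per_um: float = 0.002
    haze_amplitude: float = 150.0
    haze_scale_um: float = 40.0
    noise_sd: float = 8.0
    abu_per_fluorophore: float = 300.0

    def __post_init__(self) -> None:
        if self.attenuation_per_um < 0 or self.noise_sd < 0:
            raise ValueError("attenuation and noise must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator planted, for validating the pipeline.

    ``centers_um`` is (n, 3) with columns (z, row, col) in µm measured
    from the stack top / image origin; ``plane_index`` is the confocal
    plane each nucleus was rendered on; ``labels`` maps marker name to a
    boolean per-nucleus array (the tracker channel is keyed "Tracker").
    """

    centers_um: np.ndarray
    plane_index: np.ndarray
    radii_um: np.ndarray
    labels: dict
    labeled_fraction: float | None = None
    ablation: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)

    @property
    def n_nuclei(self) -> int:
        return self.centers_um.shape[0]

    def n_labeled(self, marker: str) -> int:
        return int(np.sum(self.labels.get(marker, np.zeros(0, dtype=bool))))

    def centers_on_plane(self, plane: int, marker: str | None = None) -> np.ndarray:
        """(row, col) µm centers of nuclei rendered on one plane."""
        sel = self.plane_index == plane
        if marker is not None:
            sel &= self.labels[marker]
        return self.centers_um[sel][:, 1:]


def _place_nuclei(
    n: int,
    radius_um: float,
    min_distance_um: float,
    rng: np.random.Generator,
    max_attempts_factor: int = 200,
) -> np.ndarray:
    """Dart-throwing placement of n points in a sphere of given radius.

    Returns (n, 3) offsets from the sphere center in µm.  Raises if the
    requested density cannot be reached.
    """
    placed = np.empty((0, 3))
    attempts = 0
    max_attempts = max(1000, max_attempts_factor * max(n, 1))
    while placed.shape[0] < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} nuclei with {min_distance_um:.1f} µm separation "
                f"in a {radius_um:.0f} µm sphere"
            )
        attempts += 1
        p = rng.uniform(-radius_um, radius_um, size=3)
        if p @ p > radius_um**2:
            continue
        if placed.size and np.min(np.sum((placed - p) ** 2, axis=1)) < min_distance_um**2:
            continue
        placed = np.vstack([placed, p])
    return placed


def _stamp_gaussian(
    plane: np.ndarray, row: float, col: float, sigma_px: float, amplitude: float
) -> None:
    """Add a 2-D Gaussian blob in place, cropped to a ±4 sigma window."""
    half = max(2, int(np.ceil(4 * sigma_px)))
    r0, r1 = int(round(row)) - half, int(round(row)) + half + 1
    c0, c1 = int(round(col)) - half, int(round(col)) + half + 1
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, plane.shape[0]), min(c1, plane.shape[1])
    if rr0 >= rr1 or cc0 >= cc1:
        return
    rows = np.arange(rr0, rr1)[:, None] - row
    cols = np.arange(cc0, cc1)[None, :] - col
    plane[rr0:rr1, cc0:cc1] += amplitude * np.exp(
        -(rows**2 + cols**2) / (2 * sigma_px**2)
    )


def _filament_texture(
    shape: tuple,
    disc_center_px: tuple,
    disc_radius_px: float,
    mean_abu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Oriented curvilinear texture: random chords inside the aggregate disc,
    lightly blurred, normalized to the requested in-disc mean intensity."""
    img = np.zeros(shape)
    if disc_radius_px < 3 or mean_abu <= 0:
        return img
    n_seg = max(4, int(disc_radius_px))
    cy, cx = disc_center_px
    for _ in range(n_seg):
        ang = rng.uniform(0, np.pi)
        off = rng.uniform(-0.9, 0.9) * disc_radius_px
        # chord at perpendicular offset `off` from the center
        half = np.sqrt(max(disc_radius_px**2 - off**2, 1.0))
        p0 = (cy + off * np.cos(ang) - half * np.sin(ang),
              cx + off * np.sin(ang) + half * np.cos(ang))
        p1 = (cy + off * np.cos(ang) + half * np.sin(ang),
              cx + off * np.sin(ang) - half * np.cos(ang))
        rr, cc = draw_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        img[rr[ok], cc[ok]] += 1.0
    img = gaussian_filter(img, 1.0)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= disc_radius_px**2
    current = img[disc].mean()
    if current > 0:
        img *= mean_abu / current
    return img


def _haze_field(
    shape: tuple,
    disc_center_px: tuple,
    halo_radius_px: float,
    amplitude: float,
    scale_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth additive background: a thickness-profile dome over the
    aggregate plus a random smooth field."""
    if amplitude <= 0:
        return np.zeros(shape)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cy, cx = disc_center_px
    if halo_radius_px > 0:
        rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / halo_radius_px**2
        dome = amplitude * np.sqrt(np.clip(1.0 - rho2, 0.0, None))
        # scattering spreads the haze well beyond sharp sample boundaries;
        # soften the thickness profile so the background is truly smooth
        dome = gaussian_filter(dome, float(np.clip(0.5 * scale_px, 2.0, 6.0)))
    else:
        dome = np.zeros(shape)
    rough = gaussian_filter(rng.standard_normal(shape), max(scale_px, 1.0))
    sd = rough.std()
    if sd > 0:
        rough *= (amplitude / 5.0) / sd
    return np.clip(dome + rough, 0.0, None)


def generate_organoid_stack(
    phenotype: OrganoidPhenotype,
    acq: AcquisitionModel | None = None,
    seed: int = 0,
    grid_shape: tuple = (256, 256),
    n_planes: int = 8,
    pixel_size_um: float = 1.0,
    plane_spacing_um: float | None = None,
    include_dapi: bool = True,
    artifacts: Sequence[Mapping] = (),
    exclusive_fractions: Mapping[str, float] | None = None,
    drop_nuclei: np.ndarray | None = None,
    lateral_offset_um: tuple = (0.0, 0.0),
    allow_partial: bool = False,
) -> tuple:
    """Render one calibrated organoid stack and its ground truth.

    The sphere is centered laterally; the z-stack covers its full height
    (default spacing 2R / n_planes, planes at slab centers).  Channels,
    in order: DAPI (nuclear), one channel per zone marker
    (nuclear-marker), the tracker channel when ``labeled_fraction`` is
    set, and one channel per filamentous marker.

    ``exclusive_fractions`` replaces the independent zone labelling with
    mutually exclusive subpopulations (used for toxin plates);
    ``drop_nuclei`` removes the flagged nuclei from the rendered scene
    (ablated cells that died and were cleared from the tissue).
    """
    acq = acq or AcquisitionModel()
    rng = np.random.default_rng(seed)
    rows_px, cols_px = grid_shape
    radius_px = phenotype.radius_um / pixel_size_um
    off_r, off_c = lateral_offset_um
    if not allow_partial and (
        radius_px + max(abs(off_r), abs(off_c)) / pixel_size_um
        >= min(rows_px, cols_px) / 2
    ):
        raise ValueError("sphere exceeds the image grid")
    spacing = plane_spacing_um or 2 * phenotype.radius_um / n_planes
    plane_z = (np.arange(n_planes) + 0.5) * spacing
    center = np.array([n_planes * spacing / 2.0,
                       rows_px * pixel_size_um / 2.0 + off_r,
                       cols_px * pixel_size_um / 2.0 + off_c])

    n = phenotype.n_nuclei
    mean_r, sd_r = phenotype.nucleus_radius_um
    offsets = _place_nuclei(
        n, phenotype.radius_um, phenotype.min_separation_factor * mean_r, rng
    )
    centers = offsets + center  # (z, row, col) µm
    radii = np.clip(rng.normal(mean_r, sd_r, size=n), 1.0, None)
    plane_idx = np.clip(
        (centers[:, 0] / spacing).astype(int), 0, n_planes - 1
    ) if n else np.zeros(0, dtype=int)

    # marker labels
    labels: dict = {}
    if exclusive_fractions is not None:
        names = sorted(exclusive_fractions)
        fracs = [exclusive_fractions[m] for m in names]
        if sum(fracs) > 1 + 1e-9:
            raise ValueError("exclusive fractions must sum to <= 1")
        # exact-count assignment: these organoids have a homogeneous
        # cellular composition well-to-well, so the subpopulation sizes
        # are fixed and only their spatial arrangement is random
        perm = rng.permutation(n)
        start = 0
        for m, f in zip(names, fracs):
            count = int(round(f * n))
            members = np.zeros(n, dtype=bool)
            members[perm[start : start + count]] = True
            labels[m] = members
            start += count
        marker_names = names
    else:
        marker_names = sorted(phenotype.zone_fractions)
        r_frac = np.linalg.norm(offsets, axis=1) / phenotype.radius_um if n else np.zeros(0)
        for m in marker_names:
            fracs = np.atleast_1d(phenotype.zone_fractions[m]).astype(float)
            zone = np.minimum((r_frac * len(fracs)).astype(int), len(fracs) - 1)
            labels[m] = rng.random(n) < fracs[zone]
    if phenotype.labeled_fraction is not None:
        labels[TRACKER] = rng.random(n) < phenotype.labeled_fraction

    keep = np.ones(n, dtype=bool)
    if drop_nuclei is not None:
        keep &= ~np.asarray(drop_nuclei, dtype=bool)

    channels = []
    if include_dapi:
        channels.append(ChannelSpec("DAPI", "nuclear"))
    channels += [ChannelSpec(m, "nuclear-marker") for m in marker_names]
    if phenotype.labeled_fraction is not None:
        channels.append(ChannelSpec(TRACKER, "nuclear-marker"))
    filament_names = sorted(phenotype.filament_density)
    channels += [ChannelSpec(m, "filamentous") for m in filament_names]

    voxels = np.zeros((len(channels), n_planes, rows_px, cols_px))
    name_to_idx = {c.name: i for i, c in enumerate(channels)}
    brightness = np.clip(rng.normal(1.0, 0.1, size=n), 0.5, None)

    # nuclear blobs, one per nucleus on its nearest plane
    for i in np.nonzero(keep)[0]:
        z, row_um, col_um = centers[i]
        p = plane_idx[i]
        amp = acq.abu_per_fluorophore * brightness[i] * np.exp(-acq.attenuation_per_um * z)
        row, col = row_um / pixel_size_um, col_um / pixel_size_um
        blob_channels = ["DAPI"] if include_dapi else []
        blob_channels += [m for m in marker_names if labels[m][i]]
        if phenotype.labeled_fraction is not None and labels[TRACKER][i]:
            blob_channels.append(TRACKER)
        for ch_name in blob_channels:
            r_blob = phenotype.marker_radius_um.get(ch_name, radii[i])
            sigma_px = max(0.8, 0.5 * r_blob / pixel_size_um)
            _stamp_gaussian(voxels[name_to_idx[ch_name], p], row, col, sigma_px, amp)

    disc_center_px = (center[1] / pixel_size_um, center[2] / pixel_size_um)
    for p, z in enumerate(plane_z):
        dz = z - center[0]
        disc_r_px = np.sqrt(max(phenotype.radius_um**2 - dz**2, 0.0)) / pixel_size_um
        atten = np.exp(-acq.attenuation_per_um * z)
        for m in filament_names:
            voxels[name_to_idx[m], p] += _filament_texture(
                grid_shape, disc_center_px, disc_r_px,
                phenotype.filament_density[m] * atten, rng,
            )
        for ci in range(len(channels)):
            voxels[ci, p] += _haze_field(
                grid_shape, disc_center_px, disc_r_px,
                acq.haze_amplitude * atten, acq.haze_scale_um / pixel_size_um, rng,
            )

    planted_artifacts = []
    for art in artifacts:
        kind = art["kind"]
        p = art.get("plane", n_planes // 2)
        amp = art.get("amplitude", 10 * acq.abu_per_fluorophore)
        if kind == "dust":
            dz = plane_z[p] - center[0]
            disc_r_px = np.sqrt(max(phenotype.radius_um**2 - dz**2, 0.0)) / pixel_size_um
            # far enough out that the 10 px aggregate dilation cannot
            # bridge the gap and absorb the particle into the region
            rho = disc_r_px + 28
            ang = art.get("angle", rng.uniform(0, 2 * np.pi))
            row = np.clip(disc_center_px[0] + rho * np.sin(ang), 4, rows_px - 5)
            col = np.clip(disc_center_px[1] + rho * np.cos(ang), 4, cols_px - 5)
            for ci in range(len(channels)):
                _stamp_gaussian(voxels[ci, p], row, col, 2.0, amp)
            planted_artifacts.append({"kind": "dust", "plane": p, "row": row, "col": col})
        elif kind == "fiber":
            r0 = int(rng.uniform(0.1, 0.3) * rows_px)
            rr, cc = draw_line(r0, 2, int(0.9 * rows_px), cols_px - 3)
            streak = np.zeros(grid_shape)
            streak[rr, cc] = amp
            streak = gaussian_filter(streak, 0.8) * 3.0
            for ci in range(len(channels)):
                voxels[ci, p] += streak
            planted_artifacts.append({"kind": "fiber", "plane": p})
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")

    if acq.noise_sd > 0:
        voxels += rng.normal(0, acq.noise_sd, size=voxels.shape)
    np.clip(voxels, 0.0, None, out=voxels)

    gt = GroundTruth(
        centers_um=centers[keep],
        plane_index=plane_idx[keep],
        radii_um=radii[keep],
        labels={m: v[keep] for m, v in labels.items()},
        labeled_fraction=phenotype.labeled_fraction,
        artifacts=planted_artifacts,
    )
    stack = ImageStack(voxels, pixel_size_um, spacing, channels)
    return stack, gt


def generate_nucleus_plane(
    n_nuclei: int,
    shape: tuple = (256, 256),
    seed: int = 0,
    amplitude: float = 300.0,
    sigma_px: float = 1.75,
    min_separation_px: float = 6.0,
    noise_sd: float = 0.0,
    haze_amplitude: float = 0.0,
    haze_scale_px: float = 40.0,
) -> tuple:
    """A single 2-D plane of non-overlapping nucleus blobs with known
    centers — the segmentation benchmark scene.

    Returns (plane, centers) with centers as an (n, 2) float array of
    (row, col) positions.
    """
    rng = np.random.default_rng(seed)
    margin = 4 * sigma_px + 2
    centers = np.empty((0, 2))
    attempts = 0
    while centers.shape[0] < n_nuclei:
        if attempts > 500 * max(n_nuclei, 1):
            raise RuntimeError("could not place the requested nuclei")
        attempts += 1
        p = rng.uniform([margin, margin], [shape[0] - margin, shape[1] - margin])
        if centers.size and np.min(np.sum((centers - p) ** 2, axis=1)) < min_separation_px**2:
            continue
        centers = np.vstack([centers, p])
    plane = np.zeros(shape)
    for row, col in centers:
        _stamp_gaussian(plane, row, col, sigma_px, amplitude)
    if haze_amplitude > 0:
        plane += _haze_field(shape, (shape[0] / 2, shape[1] / 2),
                             0.45 * min(shape), haze_amplitude, haze_scale_px, rng)
    if noise_sd > 0:
        plane += rng.normal(0, noise_sd, size=shape)
    return np.clip(plane, 0.0, None), centers


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def generate_dilution_series(
    fractions: Sequence[float],
    n_cells: int,
    acq: AcquisitionModel | None = None,
    seed: int = 0,
    replicates: int = 3,
    radius_um: float = 90.0,
    grid_shape: tuple = (256, 256),
    n_planes: int = 8,
    **stack_kwargs,
) -> list:
    """One tracker-labelled aggregate per fraction per replicate.

    Realized labelled counts are binomial draws around each requested
    fraction; both are recorded in the ground truth.  Returns records
    ``{well_id, fraction, replicate, stack, ground_truth}``.
    """
    if not len(fractions):
        raise ValueError("fraction list must be non-empty")
    if any(not 0 <= f <= 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(replicates):
        for fi, frac in enumerate(fractions):
            phen = OrganoidPhenotype(
                radius_um=radius_um,
                n_nuclei=n_cells,
                zone_fractions={},
                filament_density={},
                labeled_fraction=float(frac),
            )
            stack, gt = generate_organoid_stack(
                phen, acq, seed=_child_seed(rng), grid_shape=grid_shape,
                n_planes=n_planes, **stack_kwargs,
            )
            records.append({
                "well_id": f"{chr(ord('A') + rep)}{fi + 1}",
                "fraction": float(frac),
                "replicate": rep,
                "stack": stack,
                "ground_truth": gt,
            })
    return records


def generate_toxin_plate(
    doses: Sequence[float],
    ablation_curve: Mapping[str, Sequence[float] | Callable[[float], float]],
    seed: int = 0,
    replicates: int = 6,
    subpopulation_fractions: Mapping[str, float] | None = None,
    phenotype: OrganoidPhenotype | None = None,
    acq: AcquisitionModel | None = None,
    allow_non_monotone: bool = False,
    grid_shape: tuple = (160, 160),
    n_planes: int = 4,
    **stack_kwargs,
) -> list:
    """A dose series of organoids with marker-specific cell ablation.

    ``ablation_curve`` maps a marker to its kill fraction per dose
    (sequence aligned with ``doses``, or a callable of dose).  Killed
    cells are removed from the rendered scene entirely — dead cells are
    cleared from the tissue.  Subpopulations are mutually exclusive
    (defaults: TH 35 %, Map2 45 %).  Kill fractions must be monotone
    non-decreasing in dose unless ``allow_non_monotone``.
    Returns records ``{well_id, dose, replicate, stack, ground_truth}``.
    """
    doses = list(doses)
    subpops = dict(subpopulation_fractions or {"TH": 0.35, "Map2": 0.45})
    curves = {}
    for marker, curve in ablation_curve.items():
        kills = [float(curve(d)) for d in doses] if callable(curve) else [float(k) for k in curve]
        if len(kills) != len(doses):
            raise ValueError(f"ablation curve for {marker} does not match the dose list")
        if any(not 0 <= k <= 1 for k in kills):
            raise ValueError("kill fractions must lie in [0, 1]")
        if not allow_non_monotone and any(b < a - 1e-12 for a, b in zip(kills, kills[1:])):
            raise ValueError(f"ablation curve for {marker} is not monotone non-decreasing")
        curves[marker] = kills
    phenotype = phenotype or OrganoidPhenotype(
        radius_um=60.0, n_nuclei=300, zone_fractions={}, filament_density={},
    )
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(replicates):
        for di, dose in enumerate(doses):
            well_seed = _child_seed(rng)
            # the exclusive subpopulation labels must be known before the
            # kill draw; replay the generator's label assignment
            stack, gt = _render_toxin_well(
                phenotype, acq, well_seed, subpops,
                {m: curves[m][di] for m in curves}, rng,
                grid_shape=grid_shape, n_planes=n_planes, **stack_kwargs,
            )
            records.append({
                "well_id": f"{chr(ord('A') + rep)}{di + 1}",
                "dose": float(dose),
                "replicate": rep,
                "stack": stack,
                "ground_truth": gt,
            })
    return records


def _render_toxin_well(
    phenotype, acq, well_seed, subpops, kill_by_marker, master_rng, **stack_kwargs
):
    # first pass: labels only (cheap geometry replay is avoided by letting
    # the generator assign labels, then re-rendering with the kill mask)
    stack, gt = generate_organoid_stack(
        phenotype, acq, seed=well_seed, exclusive_fractions=subpops, **stack_kwargs
    )
    n = gt.n_nuclei
    drop = np.zeros(n, dtype=bool)
    for marker, kill in kill_by_marker.items():
        members = gt.labels[marker]
        drop |= members & (master_rng.random(n) < kill)
    if drop.any():
        stack, gt = generate_organoid_stack(
            phenotype, acq, seed=well_seed, exclusive_fractions=subpops,
            drop_nuclei=drop, **stack_kwargs,
        )
    gt.ablation = dict(kill_by_marker)
    return stack, gt


def generate_edge_effect_plate(
    effect: float = -0.10,
    layout: PlateLayout | None = None,
    seed: int = 0,
    base_density_abu: float = 60.0,
    marker: str = "Map2",
    radius_um: float = 40.0,
    n_nuclei: int = 60,
    grid_shape: tuple = (128, 128),
    n_planes: int = 4,
    acq: AcquisitionModel | None = None,
) -> list:
    """A full plate whose inside wells carry a relative change ``effect``
    in filamentous marker intensity versus the edge ring (the planted
    edge-effect; -0.10 reproduces a 10 % center reduction).

    Returns records ``{well_id, position_class, stack, ground_truth}``.
    """
    layout = layout or PlateLayout()
    acq = acq or AcquisitionModel(haze_amplitude=40.0, noise_sd=4.0)
    rng = np.random.default_rng(seed)
    records = []
    for well_id in layout.well_ids():
        pos = classify_well_position(well_id, layout)
        density = base_density_abu * (1.0 + effect if pos == "inside" else 1.0)
        phen = OrganoidPhenotype(
            radius_um=radius_um, n_nuclei=n_nuclei, zone_fractions={},
            filament_density={marker: density},
        )
        stack, gt = generate_organoid_stack(
            phen, acq, seed=_child_seed(rng), grid_shape=grid_shape, n_planes=n_planes
        )
        records.append({
            "well_id": well_id,
            "position_class": pos,
            "stack": stack,
            "ground_truth": gt,
        })
    return records


# --- time-series generators ---------------------------------------------


def planted_calcium_events(
    period_s: float, duration_s: float, until_s: float | None = None
) -> np.ndarray:
    """Event times of the synchronized spike generator: one event per
    period, centered in its period slot (period/2, 3*period/2, ...)."""
    times = np.arange(period_s / 2.0, duration_s, period_s)
    if until_s is not None:
        times = times[times < until_s]
    return times


def generate_calcium_traces(
    n_rois: int = 4,
    period_s: float = 30.0,
    spike_amplitude: float = 100.0,
    noise_sd: float = 2.0,
    rate_hz: float = 10.0,
    duration_s: float = 240.0,
    seed: int = 0,
    baseline: float = 100.0,
    decay_s: float = 2.0,
    private_rate_hz: float = 0.0,
    private_amplitude: float | None = None,
    spikes_until_s: float | None = None,
) -> TraceSet:
    """Synchronized periodic calcium spikes shared by all ROIs.

    Spikes rise instantaneously and decay exponentially (``decay_s``).
    ``private_rate_hz`` adds independent per-ROI Poisson events;
    ``spikes_until_s`` switches the synchronized events off at that time
    (the calcium-channel-blocker scenario).
    """
    if rate_hz <= 0 or duration_s <= 0:
        raise ValueError("rate and duration must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * rate_hz))
    t = np.arange(n_samples) / rate_hz
    shared = planted_calcium_events(period_s, duration_s, spikes_until_s)
    traces = np.full((n_rois, n_samples), float(baseline))
    for roi in range(n_rois):
        events = list(shared)
        if private_rate_hz > 0:
            n_private = rng.poisson(private_rate_hz * duration_s)
            events += list(rng.uniform(0, duration_s, size=n_private))
        for t0 in events:
            amp = spike_amplitude if t0 in shared else (
                private_amplitude if private_amplitude is not None else 0.7 * spike_amplitude
            )
            after = t >= t0
            traces[roi, after] += amp * np.exp(-(t[after] - t0) / decay_s)
        if noise_sd > 0:
            traces[roi] += rng.normal(0, noise_sd, size=n_samples)
    return TraceSet(t, traces, rate_hz, [f"ROI{i + 1}" for i in range(n_rois)])


def generate_calcium_movie(
    shape: tuple = (64, 64),
    rate_hz: float = 10.0,
    duration_s: float = 60.0,
    period_s: float = 20.0,
    amplitude: float = 50.0,
    baseline: float = 20.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple:
    """A small single-plane movie with aggregate-wide synchronized
    flashes; returns (movie, event_frame_indices)."""
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * rate_hz))
    t = np.arange(n_frames) / rate_hz
    events = planted_calcium_events(period_s, duration_s)
    pulse = np.zeros(n_frames)
    for t0 in events:
        after = t >= t0
        pulse[after] += amplitude * np.exp(-(t[after] - t0) / 1.0)
    movie = baseline + pulse[:, None, None] * np.ones(shape)[None]
    if noise_sd > 0:
        movie = movie + rng.normal(0, noise_sd, size=movie.shape)
    frames = np.round(events * rate_hz).astype(int)
    return np.clip(movie, 0, None), frames


def generate_field_potential(
    components: Sequence[tuple],
    rate_hz: float = 1000.0,
    duration_s: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_electrodes: int = 4,
) -> TraceSet:
    """Phase-locked sum of sinusoids per electrode plus independent noise.

    ``components`` is a sequence of (freq_hz, amplitude); every frequency
    must lie below the Nyquist limit.  The two-tone default scenario of
    synchronized network oscillations uses [(1, a), (14, b)].
    """
    rng = np.random.default_rng(seed)
    for freq, _ in components:
        if freq >= rate_hz / 2:
            raise ValueError(f"component at {freq} Hz exceeds the Nyquist limit")
    n_samples = int(round(duration_s * rate_hz))
    t = np.arange(n_samples) / rate_hz
    base = np.zeros(n_samples)
    for freq, amp in components:
        base += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    traces = np.tile(base, (n_electrodes, 1))
    if noise_sd > 0:
        traces = traces + rng.normal(0, noise_sd, size=traces.shape)
    return TraceSet(t, traces, rate_hz, [f"E{i + 1}" for i in range(n_electrodes)])
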