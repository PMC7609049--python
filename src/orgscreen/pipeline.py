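"""End-to-end runs: simulate a plate, quantify it, validate linearity.

These functions orchestrate the per-module stages over whole plates and
handle reporting: tidy per-well CSVs, batch statistics, a QC report
with per-stage sample-retention bookkeeping, and a machine-readable
provenance record (config hash, seed, package versions) sufficient to
reproduce outputs exactly.  Per-well failures are logged and skipped; a
run only aborts on configuration or I/O errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate_detection import ArtifactParams, DetectionParams, detect_aggregate, qc_classify, sum_channels
from .plate_io import PlateLayout, WellImageSet, classify_well_position, read_stack, write_results, write_stack
from .quantification import (
    SYNTHETIC_DETECTION,
    SYNTHETIC_NUCLEUS_GATE,
    SYNTHETIC_SEGMENTATION,
    batch_cv,
    dilution_linearity,
    quantify_filamentous_marker,
    quantify_nuclear_marker,
)
from .background_correction import BackgroundSpec
from .dose_response import fit_sigmoid, normalize_to_control
from .quantification import edge_effect_report
from .segmentation import SegmentationParams
from .synthetic_data import (
    AcquisitionModel,
    OrganoidPhenotype,
    generate_dilution_series,
    generate_edge_effect_plate,
    generate_organoid_stack,
    generate_toxin_plate,
)

logger = logging.getLogger(__name__)


def provenance_record(config: dict, seed: int) -> dict:
    """Reproducibility fingerprint written next to every run's outputs."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    versions = {"orgscreen": __version__, "numpy": np.__version__, "pandas": pd.__version__}
    return {"config_sha256": hashlib.sha256(blob).hexdigest(), "seed": seed,
            "versions": versions}


def simulate_plate(
    seed: int = 0,
    n_wells: int = 24,
    dust_wells: tuple = (),
    layout: PlateLayout | None = None,
    phenotype: OrganoidPhenotype | None = None,
    acq: AcquisitionModel | None = None,
    grid_shape: tuple = (192, 192),
    n_planes: int = 6,
) -> list:
    """A demo plate of small organoid stacks; ``dust_wells`` get a
    planted dust artifact as QC positive controls.  Returns records
    ``{well_id, stack, ground_truth}``."""
    layout = layout or PlateLayout()
    phenotype = phenotype or OrganoidPhenotype(
        radius_um=60.0, n_nuclei=400, zone_fractions={"Sox2": (0.8, 0.45, 0.15)},
        filament_density={"Map2": 60.0},
    )
    rng = np.random.default_rng(seed)
    records = []
    for well_id in layout.well_ids()[:n_wells]:
        artifacts = [{"kind": "dust"}] if well_id in dust_wells else []
        stack, gt = generate_organoid_stack(
            phenotype, acq, seed=int(rng.integers(0, 2**31 - 1)),
            grid_shape=grid_shape, n_planes=n_planes, artifacts=artifacts,
        )
        records.append({"well_id": well_id, "stack": stack, "ground_truth": gt})
    return records


def run_simulate(config: dict, output_dir: str | Path, seed: int | None = None) -> Path:
    """Write a synthetic plate to disk: stacks, ground-truth CSV, manifest."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    records = simulate_plate(
        seed=seed,
        n_wells=int(config.get("n_wells", 24)),
        dust_wells=tuple(config.get("dust_wells", ())),
    )
    manifest = {"kind": "demo_plate", "seed": seed, "wells": []}
    gt_rows = []
    for rec in records:
        path = output_dir / f"{rec['well_id']}.tiff"
        write_stack(rec["stack"], path)
        manifest["wells"].append({"well_id": rec["well_id"], "path": path.name})
        gt = rec["ground_truth"]
        for i in range(gt.n_nuclei):
            row = {"well_id": rec["well_id"], "plane": int(gt.plane_index[i]),
                   "z_um": gt.centers_um[i, 0], "row_um": gt.centers_um[i, 1],
                   "col_um": gt.centers_um[i, 2]}
            row.update({f"label_{m}": bool(v[i]) for m, v in gt.labels.items()})
            gt_rows.append(row)
    pd.DataFrame(gt_rows).to_csv(output_dir / "ground_truth.csv", index=False)
    with open(output_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    with open(output_dir / "provenance.json", "w") as fh:
        json.dump(provenance_record(config, seed), fh, indent=2, sort_keys=True)
    return output_dir


def quantify_plate(
    records: list,
    nuclear_markers: tuple = ("Sox2",),
    filament_markers: tuple = ("Map2",),
    layout: PlateLayout | None = None,
    detection: DetectionParams = SYNTHETIC_DETECTION,
    gate=SYNTHETIC_NUCLEUS_GATE,
    segmentation=SYNTHETIC_SEGMENTATION,
    artifact_params: ArtifactParams = ArtifactParams(),
) -> dict:
    """QC + quantification of an in-memory plate.

    Returns ``{"summaries": [...], "verdicts": {...}, "retention": {...}}``;
    QC-failed wells are reported but not quantified.
    """
    layout = layout or PlateLayout()
    summaries, verdicts = [], {}
    n_total = len(records)
    for rec in records:
        well = WellImageSet(rec["well_id"], [rec["stack"]])
        fov = rec["stack"]
        regions = {}
        summed = sum_channels(fov).voxels[0]
        for p in range(fov.n_planes):
            regions[(0, p)] = detect_aggregate(summed[p], fov.pixel_size_um, detection, p)
        verdict = qc_classify(well, regions, artifact_params, detection)
        verdicts[rec["well_id"]] = verdict
        if not verdict.qc_pass:
            logger.warning("well %s rejected: %s", rec["well_id"], sorted(verdict.reasons))
            continue
        pos = classify_well_position(rec["well_id"], layout)
        for marker in nuclear_markers:
            if marker not in fov.channel_names:
                continue
            s = quantify_nuclear_marker(well, marker, gate, detection,
                                        segmentation=segmentation)
            s.position_class = pos
            summaries.append(s)
        for marker in filament_markers:
            if marker not in fov.channel_names:
                continue
            s = quantify_filamentous_marker(well, marker, detection)
            s.position_class = pos
            summaries.append(s)
    n_pass = sum(1 for v in verdicts.values() if v.qc_pass)
    retention = {
        "n_wells": n_total,
        "n_qc_pass": n_pass,
        "fraction_passing_qc": n_pass / n_total if n_total else float("nan"),
    }
    return {"summaries": summaries, "verdicts": verdicts, "retention": retention}


def run_quantify(config: dict, plate_dir: str | Path, output_dir: str | Path) -> dict:
    """Quantify a simulated plate directory; write result/QC/batch tables."""
    plate_dir, output_dir = Path(plate_dir), Path(output_dir)
    with open(plate_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    records = []
    for entry in manifest["wells"]:
        stack = read_stack(plate_dir / entry["path"])
        records.append({"well_id": entry["well_id"], "stack": stack})
    result = quantify_plate(records)
    output_dir.mkdir(parents=True, exist_ok=True)
    write_results(result["summaries"], output_dir / "well_summaries.csv")
    batch_rows = []
    for marker in sorted({s.marker for s in result["summaries"]}):
        vals = [s.n_objects if s.n_objects else s.filament_intensity_abu
                for s in result["summaries"] if s.marker == marker]
        if len(vals) >= 2 and np.mean(vals) != 0:
            st = batch_cv(vals, marker)
            batch_rows.append({"marker": marker, "mean": st.mean, "sd": st.sd,
                               "cv": st.cv, "n": st.n})
    pd.DataFrame(batch_rows).to_csv(output_dir / "batch_stats.csv", index=False)
    qc_report = {
        "retention": result["retention"],
        "rejected": {w: sorted(v.reasons) for w, v in result["verdicts"].items()
                     if not v.qc_pass},
    }
    with open(output_dir / "qc_report.json", "w") as fh:
        json.dump(qc_report, fh, indent=2, sort_keys=True)
    with open(output_dir / "provenance.json", "w") as fh:
        json.dump(provenance_record(config, int(manifest.get("seed", 0))), fh,
                  indent=2, sort_keys=True)
    return qc_report


def run_validate_linearity(
    seed: int = 0,
    fractions: tuple = (0.0125, 0.025, 0.05, 0.1, 0.2, 0.4),
    sizes: dict | None = None,
    replicates: int = 3,
    r2_threshold: float = 0.99,
    output_path: str | Path | None = None,
) -> dict:
    """Dilution-series linearity validation (tracked-cell quantification).

    Generates labelled aggregates at the given fractions for each size
    class, runs the full nuclear quantification on the tracker channel,
    regresses summed labelled brightness on fraction, and reports per-size
    R² with a PASS flag at ``r2_threshold``.
    """
    sizes = sizes or {"small": {"n_cells": 1000, "radius_um": 90.0},
                      "large": {"n_cells": 2000, "radius_um": 115.0}}
    rng = np.random.default_rng(seed)
    report = {"r2_threshold": r2_threshold, "sizes": {}}
    for name, spec in sizes.items():
        records = generate_dilution_series(
            fractions, spec["n_cells"], seed=int(rng.integers(0, 2**31 - 1)),
            replicates=replicates, radius_um=spec["radius_um"],
        )
        xs, ys = [], []
        for rec in records:
            well = WellImageSet(rec["well_id"], [rec["stack"]])
            s = quantify_nuclear_marker(well, "Tracker", SYNTHETIC_NUCLEUS_GATE)
            xs.append(rec["fraction"])
            ys.append(s.total_brightness_abu)
        fit = dilution_linearity(xs, ys)
        fit["pass"] = bool(fit["r_squared"] >= r2_threshold)
        report["sizes"][name] = fit
    report["pass"] = all(v["pass"] for v in report["sizes"].values())
    if output_path is not None:
        Path(output_path).parent.mkdir(parents=True, exist_ok=True)
        with open(output_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def four_pl_kill_curve(ec50: float, hill: float = 1.5, max_kill: float = 0.9):
    """A monotone dose -> kill-fraction curve of logistic shape; the
    corresponding survival is a 4PL with top 1, bottom 1 - max_kill."""

    def kill(dose: float) -> float:
        if dose <= 0:
            return 0.0
        return max_kill / (1.0 + (ec50 / dose) ** hill)

    return kill


#: study conditions of the scaled-down toxicity assay; chosen once from
#: the generator design (small organoids, soma-scale markers, mild haze)
TOXIN_PHENOTYPE = OrganoidPhenotype(
    radius_um=60.0, n_nuclei=240, zone_fractions={}, filament_density={},
    marker_radius_um={"TH": 4.0, "Map2": 4.0},
)
TOXIN_ACQUISITION = AcquisitionModel(haze_amplitude=60.0, noise_sd=6.0)
TOXIN_SEGMENTATION = SegmentationParams(expected_diameter_um=10.0, detection_threshold=60.0)
#: high-pass widths per channel used for the soma-scale markers
TOXIN_BACKGROUND = {
    "TH": BackgroundSpec("highpass", width_px=10.0),
    "Map2": BackgroundSpec("highpass", width_px=5.0),
}


def run_toxicity_assay(
    seed: int = 0,
    doses: tuple = (0.0, 50.0, 100.0, 250.0, 500.0),
    ablation_curve: dict | None = None,
    replicates: int = 6,
    markers: tuple = ("TH", "Map2"),
    compound: str = "6-OHDA",
) -> dict:
    """Generate a toxin plate, quantify both markers, normalize to
    control, and fit 4PL curves; the full subpopulation-toxicity flow.

    By default a TH-specific kill curve (EC50 100, Hill 1.5, 90 % max
    kill) is planted while Map2 neurons are spared.  Returns
    ``{"series": DoseSeries, "fits": {marker: ...}, "records": [...]}``.
    """
    ablation_curve = ablation_curve or {"TH": four_pl_kill_curve(100.0)}
    records = generate_toxin_plate(
        doses, ablation_curve, seed=seed, replicates=replicates,
        phenotype=TOXIN_PHENOTYPE, acq=TOXIN_ACQUISITION,
        subpopulation_fractions={"TH": 0.2, "Map2": 0.3}, n_planes=6,
    )
    summaries, annotations = [], {}
    for rec in records:
        well = WellImageSet(rec["well_id"], [rec["stack"]])
        for marker in markers:
            summaries.append(quantify_nuclear_marker(
                well, marker, SYNTHETIC_NUCLEUS_GATE,
                background=TOXIN_BACKGROUND.get(marker),
                segmentation=TOXIN_SEGMENTATION, finder="cells",
            ))
        annotations[rec["well_id"]] = {"dose": rec["dose"], "replicate": rec["replicate"]}
    series = normalize_to_control(summaries, annotations, compound=compound)
    fits = {m: fit_sigmoid(series, m, seed=seed) for m in markers}
    return {"series": series, "fits": fits, "records": records}


def run_edge_effect_assay(
    seed: int = 0, effect: float = -0.10, marker: str = "Map2", n_boot: int = 10_000
) -> dict:
    """Generate a 96-well plate with a planted center reduction in a
    filamentous marker, quantify it, and report the edge-vs-inside
    comparison with a seeded bootstrap CI."""
    records = generate_edge_effect_plate(effect=effect, seed=seed, marker=marker)
    summaries = []
    for rec in records:
        s = quantify_filamentous_marker(WellImageSet(rec["well_id"], [rec["stack"]]), marker)
        s.position_class = rec["position_class"]
        summaries.append(s)
    return edge_effect_report(summaries, marker, n_boot=n_boot, seed=seed)
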