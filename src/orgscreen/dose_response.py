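"""Subpopulation-specific toxicity analysis across a dose series.

Per-marker readouts (area-normalized total brightness by default) are
normalized to the vehicle-control (dose 0) mean, giving survival-like
values with control mean exactly 1.  Specificity of a toxin for one
subpopulation shows as the target/reference ratio falling below 1 with
dose.  A four-parameter logistic (4PL) fit in log-dose summarises the
curve (top, bottom, EC50, Hill slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .quantification import WellSummary


@dataclass
class DoseSeries:
    """Normalized per-dose, per-marker values with replicate spread.

    ``table`` is tidy: columns (marker, dose, replicate, value); doses
    strictly increasing; control (dose 0) values average to exactly 1
    per marker by construction.
    """

    compound: str
    doses: np.ndarray
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.size and not np.all(np.diff(self.doses) > 0):
            raise ValueError("doses must be strictly increasing")

    @property
    def markers(self) -> list:
        return sorted(self.table["marker"].unique())

    def values(self, marker: str, dose: float) -> np.ndarray:
        sel = (self.table["marker"] == marker) & (self.table["dose"] == dose)
        return self.table.loc[sel, "value"].to_numpy()

    def means(self, marker: str) -> np.ndarray:
        return np.array([self.values(marker, d).mean() for d in self.doses])


def normalize_to_control(
    summaries: Sequence[WellSummary],
    annotations: Mapping[str, Mapping],
    compound: str = "",
    metric: str = "total_brightness_abu",
    area_normalize: bool = True,
) -> DoseSeries:
    """Build a DoseSeries from per-well summaries and dose annotations.

    ``annotations`` maps well_id -> {"dose": float, optionally
    "replicate": int}.  Area normalization (metric / summed aggregate
    area) precedes control normalization.  Each marker needs at least
    one dose-0 control well.
    """
    rows = []
    for s in summaries:
        ann = annotations.get(s.well_id)
        if ann is None:
            continue
        raw = getattr(s, metric)
        if area_normalize:
            if s.aggregate_area_um2 <= 0:
                raise ZeroDivisionError(f"well {s.well_id}: aggregate area is zero")
            raw = raw / s.aggregate_area_um2
        rows.append({
            "marker": s.marker,
            "dose": float(ann["dose"]),
            "replicate": int(ann.get("replicate", 0)),
            "value": float(raw),
        })
    if not rows:
        raise ValueError("no annotated wells")
    table = pd.DataFrame(rows)
    doses = np.sort(table["dose"].unique())
    for marker, group in table.groupby("marker"):
        controls = group.loc[group["dose"] == 0.0, "value"]
        if controls.empty:
            raise ValueError(f"no dose-0 control wells for marker {marker}")
        table.loc[table["marker"] == marker, "value"] /= controls.mean()
    return DoseSeries(compound=compound, doses=doses, table=table)


def specificity_profile(
    series: DoseSeries, marker_target: str, marker_reference: str
) -> pd.DataFrame:
    """Per-dose ratio of target to reference normalized means.

    A ratio below 1 that falls with dose indicates target-specific loss
    (e.g. dopaminergic neurons ablated while general neurons persist).
    The Spearman correlation of ratio vs dose is attached as
    ``frame.attrs["spearman_rho"]``.
    """
    target = series.means(marker_target)
    reference = series.means(marker_reference)
    if np.any(reference == 0):
        raise ZeroDivisionError("reference value is zero at some dose")
    ratio = target / reference
    frame = pd.DataFrame({"dose": series.doses, "ratio": ratio})
    if np.unique(ratio).size > 1:
        from scipy.stats import spearmanr

        frame.attrs["spearman_rho"] = float(spearmanr(series.doses, ratio).statistic)
    else:
        frame.attrs["spearman_rho"] = 0.0
    return frame


def _four_pl(logd: np.ndarray, top: float, bottom: float, log_ec50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10 ** (hill * (logd - log_ec50)))


def fit_sigmoid(series: DoseSeries, marker: str, seed: int = 0) -> dict:
    """Four-parameter logistic fit in log-dose (seeded multi-start).

    Dose 0 is placed one decade below the lowest nonzero dose on the log
    axis.  Bounds: bottom >= 0, top <= 1.5.  Returns top, bottom, ec50,
    hill_slope, r_squared, plus ``converged`` and ``degenerate`` flags
    (a flat series cannot constrain an EC50); non-convergence is
    reported, never raised.
    """
    if series.doses.size < 4:
        raise ValueError("need at least four doses")
    sub = series.table[series.table["marker"] == marker]
    doses = sub["dose"].to_numpy()
    values = sub["value"].to_numpy()
    nonzero = series.doses[series.doses > 0]
    pseudo_zero = nonzero.min() / 10.0
    logd = np.log10(np.where(doses > 0, doses, pseudo_zero))
    result = {"marker": marker, "converged": False, "degenerate": False,
              "top": np.nan, "bottom": np.nan, "ec50": np.nan,
              "hill_slope": np.nan, "r_squared": np.nan}
    if np.ptp(values) < 0.05:
        result["degenerate"] = True
        return result
    rng = np.random.default_rng(seed)
    bounds = ([0.0, 0.0, np.log10(pseudo_zero) - 1, 0.2],
              [1.5, 1.5, np.log10(series.doses.max()) + 1, 5.0])
    best, best_sse = None, np.inf
    starts = [np.log10(nonzero.min()), np.log10(np.median(nonzero)), np.log10(nonzero.max())]
    starts += list(rng.uniform(np.log10(pseudo_zero), np.log10(series.doses.max()), 3))
    for log_ec50_0 in starts:
        p0 = [min(values.max(), 1.5), max(values.min(), 0.0), log_ec50_0, 1.0]
        try:
            popt, _ = curve_fit(_four_pl, logd, values, p0=p0, bounds=bounds, maxfev=5000)
        except RuntimeError:
            continue
        sse = float(np.sum((values - _four_pl(logd, *popt)) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        return result
    sst = float(np.sum((values - values.mean()) ** 2))
    result.update({
        "converged": True,
        "top": float(best[0]),
        "bottom": float(best[1]),
        "ec50": float(10 ** best[2]),
        "hill_slope": float(best[3]),
        "r_squared": 1.0 - best_sse / sst if sst > 0 else np.nan,
    })
    if abs(result["top"] - result["bottom"]) < 0.1:
        result["degenerate"] = True
    return result
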