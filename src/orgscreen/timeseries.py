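"""Functional readouts: calcium traces and synchrony, MEA oscillations.

Covers ROI mean-fluorescence extraction from movies, ΔF/F₀ spike
detection with a rolling-percentile baseline, synchrony measures,
Savitzky-Golay pre-smoothing, the 15-s absolute-sum oscillation metric
relative to basal conditions, and Blackman-windowed FFT spectra with
dominant-peak extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import percentile_filter

logger = logging.getLogger(__name__)


@dataclass
class TraceSet:
    """Uniformly sampled per-ROI / per-electrode traces.

    ``traces`` is (n_traces, n_samples); ``names`` labels the rows.
    """

    time_s: np.ndarray
    traces: np.ndarray
    rate_hz: float
    names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[1] != self.time_s.size:
            raise ValueError("traces and time axis disagree in length")
        if not self.names:
            self.names = [f"trace_{i}" for i in range(self.traces.shape[0])]
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("sampling must be uniform")

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0]

    def to_csv(self, path: str | Path) -> Path:
        frame = pd.DataFrame({"time_s": self.time_s})
        for name, tr in zip(self.names, self.traces):
            frame[name] = tr
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraceSet":
        frame = pd.read_csv(path)
        time_s = frame["time_s"].to_numpy()
        names = [c for c in frame.columns if c != "time_s"]
        rate = 1.0 / float(time_s[1] - time_s[0]) if time_s.size > 1 else 1.0
        return cls(time_s, frame[names].to_numpy().T, rate, names)


@dataclass
class SpikeTrain:
    """Detected events of one trace: times (s, strictly increasing) and
    per-event ΔF/F₀ amplitudes."""

    times_s: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.times_s.size


def quadrant_rois(shape: tuple) -> dict:
    """Four quadrant masks of a (rows, cols) frame, for the classic
    whole-aggregate vs quadrant synchrony comparison."""
    rows, cols = shape
    r2, c2 = rows // 2, cols // 2
    masks = {}
    for name, (rs, cs) in {
        "Q1": (slice(0, r2), slice(0, c2)),
        "Q2": (slice(0, r2), slice(c2, cols)),
        "Q3": (slice(r2, rows), slice(0, c2)),
        "Q4": (slice(r2, rows), slice(c2, cols)),
    }.items():
        m = np.zeros(shape, dtype=bool)
        m[rs, cs] = True
        masks[name] = m
    return masks


def extract_roi_traces(
    movie: np.ndarray, rois: Mapping[str, np.ndarray], rate_hz: float
) -> TraceSet:
    """Per-frame mean intensity of each ROI mask over a (T, R, C) movie."""
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 1:
        raise ValueError("movie must be (frames, rows, cols) with >= 1 frame")
    names, traces = [], []
    for name, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"ROI {name!r} is empty")
        names.append(name)
        traces.append(movie[:, mask].mean(axis=1))
    time_s = np.arange(movie.shape[0]) / rate_hz
    return TraceSet(time_s, np.array(traces), rate_hz, names)


def detect_spikes(
    trace: np.ndarray,
    rate_hz: float,
    baseline_percentile: float = 10.0,
    baseline_window_s: float = 30.0,
    threshold_mads: float = 3.0,
    min_separation_s: float = 1.0,
) -> SpikeTrain:
    """Detect calcium events on a single trace via ΔF/F₀ thresholding.

    F₀ is a rolling lower-percentile baseline; events are samples where
    ΔF/F₀ exceeds ``threshold_mads`` robust standard deviations
    (1.4826 x MAD), merged when closer than ``min_separation_s``.  A
    zero-variance trace yields an empty train.
    """
    trace = np.asarray(trace, dtype=float)
    window = int(round(baseline_window_s * rate_hz))
    if trace.size <= window:
        raise ValueError("trace shorter than the baseline window")
    if np.ptp(trace) == 0:
        return SpikeTrain(np.empty(0), np.empty(0))
    f0 = percentile_filter(trace, baseline_percentile, size=window, mode="nearest")
    f0 = np.maximum(f0, 1e-12)
    dff = (trace - f0) / f0
    med = np.median(dff)
    mad = np.median(np.abs(dff - med))
    if mad == 0:
        return SpikeTrain(np.empty(0), np.empty(0))
    threshold = med + threshold_mads * 1.4826 * mad
    above = np.nonzero(dff > threshold)[0]
    if above.size == 0:
        return SpikeTrain(np.empty(0), np.empty(0))
    min_gap = max(1, int(round(min_separation_s * rate_hz)))
    groups = np.split(above, np.nonzero(np.diff(above) > min_gap)[0] + 1)
    times, amps = [], []
    for grp in groups:
        peak = grp[np.argmax(dff[grp])]
        times.append(peak / rate_hz)
        amps.append(dff[peak])
    return SpikeTrain(np.array(times), np.array(amps))


def synchrony_index(
    traces: TraceSet | None = None,
    trains: Sequence[SpikeTrain] | None = None,
    window_s: float = 0.5,
) -> dict:
    """Quantify aggregate-wide synchrony.

    ``pairwise_correlation_mean`` is the mean Pearson correlation over
    all trace pairs; ``coactive_fraction`` the fraction of event groups
    (events clustered across trains within ±``window_s``) in which every
    train participates.  Identical traces give 1.0 for both.
    """
    out: dict = {}
    if traces is not None:
        if traces.n_traces < 2:
            raise ValueError("need at least two traces")
        corr = np.corrcoef(traces.traces)
        iu = np.triu_indices(traces.n_traces, k=1)
        out["pairwise_correlation_mean"] = float(np.nanmean(corr[iu]))
    if trains is not None:
        if len(trains) < 2:
            raise ValueError("need at least two spike trains")
        events = sorted(
            (t, i) for i, train in enumerate(trains) for t in train.times_s
        )
        groups: list = []
        for t, i in events:
            if groups and t - groups[-1]["t_last"] <= window_s:
                groups[-1]["members"].add(i)
                groups[-1]["t_last"] = t
            else:
                groups.append({"members": {i}, "t_last": t})
        if groups:
            coactive = sum(1 for g in groups if len(g["members"]) == len(trains))
            out["coactive_fraction"] = coactive / len(groups)
        else:
            out["coactive_fraction"] = float("nan")
    return out


def sg_smooth(trace: np.ndarray, window_samples: int = 50, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing (peak-preserving noise removal).

    Even window sizes — the conventional setting is 50 — are adjusted up
    by one sample, since the filter needs a center point; the adjustment
    is logged.  Polynomials up to ``polyorder`` pass unchanged.
    """
    trace = np.asarray(trace, dtype=float)
    if window_samples % 2 == 0:
        logger.info("Savitzky-Golay window %d adjusted to %d (odd required)",
                    window_samples, window_samples + 1)
        window_samples += 1
    if window_samples > trace.size:
        raise ValueError("window longer than trace")
    if polyorder >= window_samples:
        raise ValueError("polyorder must be smaller than the window")
    return signal.savgol_filter(trace, window_samples, polyorder)


def oscillation_metric(
    trace_basal: np.ndarray,
    trace_treated: np.ndarray,
    rate_hz: float,
    window_s: float = 15.0,
    sg_window: int = 50,
    polyorder: int = 3,
    offset_s: float = 0.0,
) -> float:
    """Total absolute field-potential oscillation relative to basal.

    Each trace segment (``window_s`` starting at ``offset_s``) is
    Savitzky-Golay smoothed and mean-removed, then the ratio
    sum(|treated|) / sum(|basal|) is returned: 1.0 means unchanged
    activity, 2.0 a doubled oscillation amplitude.
    """
    n = int(round(window_s * rate_hz))
    i0 = int(round(offset_s * rate_hz))
    segs = []
    for trace in (trace_basal, trace_treated):
        trace = np.asarray(trace, dtype=float)
        if trace.size < i0 + n:
            raise ValueError("trace shorter than the analysis window")
        seg = sg_smooth(trace[i0 : i0 + n], sg_window, polyorder)
        segs.append(seg - seg.mean())
    basal_sum = np.abs(segs[0]).sum()
    if basal_sum == 0:
        raise ValueError("basal oscillation sum is zero")
    return float(np.abs(segs[1]).sum() / basal_sum)


def spectrum(
    trace: np.ndarray,
    rate_hz: float,
    window: str = "blackman",
    peak_floor_factor: float = 50.0,
    min_relative_power: float = 1e-6,
) -> dict:
    """Windowed FFT power spectrum with dominant-peak extraction.

    The mean-removed trace is tapered (Blackman by default) and the
    one-sided power spectrum computed.  Dominant peaks are local maxima
    whose power exceeds ``peak_floor_factor`` times the median spectral
    power (a noise-floor estimate) and ``min_relative_power`` times the
    spectral maximum (so numerical leakage in near-noiseless signals
    never counts), sorted by descending power.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2 or trace.size / rate_hz < 2.0:
        raise ValueError("need at least 2 s of data")
    x = trace - trace.mean()
    taper = signal.get_window(window, trace.size)
    spec = np.fft.rfft(x * taper)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(trace.size, d=1.0 / rate_hz)
    floor = max(peak_floor_factor * float(np.median(power)),
                min_relative_power * float(power.max()),
                np.finfo(float).tiny)
    idx, _ = signal.find_peaks(power, height=floor)
    order = np.argsort(power[idx])[::-1]
    peaks = [(float(freqs[i]), float(power[i])) for i in idx[order]]
    return {"frequencies": freqs, "power": power, "dominant_peaks": peaks}
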