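"""Fiber-photometry processing: smoothing, dF/F, robust z and epoch peaks.

The chain mirrors standard event-locked photometry analysis: the 1-kHz
raw fluorescence is smoothed with a 50-ms running average and downsampled
to 50 samples/s; each trial is baselined to the mean of the 500 ms
preceding the trial start (dF/F = (F - B) / B); dF/F segments are
normalized per session with a robust z score (median / median absolute
deviation over the analyzed trial sections); and per-epoch amplitudes are
the signed peak-or-valley of larger prominence inside region-specific
windows.

Epoch windows (striatal subregions differ in sensor/release kinetics):
cue, 1,000 ms from cue onset for all regions; spouts, 340 ms from cue
offset; outcome, a window starting 160 ms (VS, DMS) or 140 ms (DLS) after
the instrumental lick and lasting 840 ms (VS), 740 ms (DMS) or 380 ms
(DLS).  Plain window means are available as a cross-check variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

REGIONS = ("VS", "DMS", "DLS")

RAW_FS = 1000.0
PROCESSED_FS = 50.0


@dataclass(frozen=True)
class EpochWindows:
    """Per-region epoch windows, in seconds."""

    region: str
    cue_s: float = 1.0
    spouts_s: float = 0.34
    outcome_len_s: float = 0.84
    outcome_latency_s: float = 0.16


_WINDOWS = {
    "VS": EpochWindows("VS", outcome_len_s=0.84, outcome_latency_s=0.16),
    "DMS": EpochWindows("DMS", outcome_len_s=0.74, outcome_latency_s=0.16),
    "DLS": EpochWindows("DLS", outcome_len_s=0.38, outcome_latency_s=0.14),
}


def epoch_windows(region: str) -> EpochWindows:
    try:
        return _WINDOWS[region]
    except KeyError:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}") from None


@dataclass
class RawTrace:
    """Continuous fluorescence at 1 kHz with event timestamps (seconds)."""

    values: np.ndarray
    events: Mapping[str, np.ndarray]
    fs: float = RAW_FS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.events = {k: np.asarray(v, dtype=float) for k, v in self.events.items()}
        duration = len(self.values) / self.fs
        for name, ts in self.events.items():
            if np.any(np.diff(ts) <= 0):
                raise ValueError(f"event timestamps {name!r} must be strictly increasing")
            if ts.size and (ts[0] < 0 or ts[-1] > duration):
                raise ValueError(f"event timestamps {name!r} fall outside the trace")


@dataclass
class ProcessedTrace:
    """Smoothed, downsampled trace (50 samples/s) sharing the raw clock."""

    values: np.ndarray
    events: Mapping[str, np.ndarray]
    fs: float = PROCESSED_FS


def smooth_downsample(trace: RawTrace, smooth_s: float = 0.05,
                      target_fs: float = PROCESSED_FS) -> ProcessedTrace:
    """Centered running average then decimation (1 kHz -> 50 Hz by default).

    The moving-average window shrinks at the edges; the decimator keeps
    every ``fs / target_fs``-th sample starting at sample 0, so a trace of
    n samples yields ceil(n / 20) samples.
    """
    window = max(1, int(round(smooth_s * trace.fs)))
    factor = int(round(trace.fs / target_fs))
    smoothed = (
        pd.Series(trace.values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return ProcessedTrace(values=smoothed[::factor], events=dict(trace.events),
                          fs=trace.fs / factor)


# ---------------------------------------------------------------------------
# dF/F and normalization
# ---------------------------------------------------------------------------

@dataclass
class TrialSegments:
    """Per-trial dF/F segments cut at trial starts."""

    segments: list[np.ndarray]
    baselines: np.ndarray
    valid: np.ndarray
    start_indices: np.ndarray
    fs: float


def dff(proc: ProcessedTrace, trial_start_times: np.ndarray | None = None,
        baseline_s: float = 0.5) -> TrialSegments:
    """Per-trial dF/F: (F - B) / B with B the mean of the pre-trial baseline.

    Trials run from one trial start to the next (the last to the end of
    the trace).  A non-positive baseline flags the trial invalid rather
    than producing unbounded values.
    """
    if trial_start_times is None:
        trial_start_times = np.asarray(proc.events["trial_start"])
    starts = np.round(np.asarray(trial_start_times) * proc.fs).astype(int)
    nb = int(round(baseline_s * proc.fs))
    bounds = np.append(starts, len(proc.values))
    segments, baselines, valid = [], [], []
    for i, s in enumerate(starts):
        base = proc.values[max(0, s - nb): s]
        b = float(np.mean(base)) if base.size else np.nan
        seg = proc.values[s: bounds[i + 1]]
        ok = np.isfinite(b) and b > 0
        segments.append((seg - b) / b if ok else np.full_like(seg, np.nan))
        baselines.append(b)
        valid.append(ok)
    return TrialSegments(segments=segments, baselines=np.asarray(baselines),
                         valid=np.asarray(valid), start_indices=starts, fs=proc.fs)


@dataclass
class RobustZ:
    values: np.ndarray
    median: float
    mad: float
    degenerate: bool

    def invert(self) -> np.ndarray:
        return self.values * self.mad + self.median


def robust_z(values: np.ndarray, reference: np.ndarray | None = None) -> RobustZ:
    """(x - median) / MAD with statistics taken from ``reference`` (default: x).

    The reference is typically the concatenated analyzed trial segments of
    a session.  A zero MAD flags the session degenerate; values are then
    only median-subtracted.
    """
    values = np.asarray(values, dtype=float)
    ref = values if reference is None else np.asarray(reference, dtype=float)
    ref = ref[np.isfinite(ref)]
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    if mad == 0.0:
        return RobustZ(values=values - med, median=med, mad=0.0, degenerate=True)
    return RobustZ(values=(values - med) / mad, median=med, mad=mad, degenerate=False)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def _dominant(segment: np.ndarray) -> tuple[float, int] | None:
    """(prominence, index) of the most prominent local maximum, or None."""
    idx, props = find_peaks(segment, prominence=0.0)
    if idx.size == 0:
        return None
    best = int(np.argmax(props["prominences"]))
    return float(props["prominences"][best]), int(idx[best])


def detect_peak(segment: np.ndarray, fs: float = PROCESSED_FS) -> tuple[float, float]:
    """Signed amplitude and latency of the dominant transient in a window.

    The most prominent local peak and the most prominent local valley
    (found on the sign-inverted segment) compete; the one with the larger
    prominence wins, ties going to the peak.  The amplitude is the segment
    value at that extremum (negative for a valley).  Windows without any
    interior local extremum fall back to the largest-magnitude sample.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0 or not np.all(np.isfinite(segment)):
        return float("nan"), float("nan")
    pos = _dominant(segment)
    neg = _dominant(-segment)
    if pos is None and neg is None:
        i = int(np.argmax(np.abs(segment)))
    elif neg is None or (pos is not None and pos[0] >= neg[0]):
        i = pos[1]
    else:
        i = neg[1]
    return float(segment[i]), i / fs


# ---------------------------------------------------------------------------
# Epoch amplitudes
# ---------------------------------------------------------------------------

def epoch_amplitudes(proc: ProcessedTrace, region: str, method: str = "peak",
                     normalize: bool = True, baseline_s: float = 0.5) -> pd.DataFrame:
    """Per-trial cue / spouts / outcome amplitudes for one session.

    Runs the dF/F -> robust-z -> windowed peak chain on a processed trace
    whose events provide ``trial_start``, ``cue_onset``, ``cue_offset``
    and ``lick`` timestamps per trial.  ``method="mean"`` replaces the
    prominence-based peak with the plain window average (latency NaN).
    Latencies are reported relative to each window's start.
    """
    if method not in ("peak", "mean"):
        raise ValueError(f"unknown method {method!r}")
    win = epoch_windows(region)
    segs = dff(proc, baseline_s=baseline_s)
    concat = np.concatenate([s for s, ok in zip(segs.segments, segs.valid) if ok]) \
        if np.any(segs.valid) else np.array([])
    if normalize and concat.size:
        z = robust_z(concat)
        segments = [(s - z.median) / z.mad if not z.degenerate else s - z.median
                    for s in segs.segments]
    else:
        segments = segs.segments
    starts = np.asarray(proc.events["trial_start"])
    anchors = {
        "cue": (np.asarray(proc.events["cue_onset"]), 0.0, win.cue_s),
        "spouts": (np.asarray(proc.events["cue_offset"]), 0.0, win.spouts_s),
        "outcome": (np.asarray(proc.events["lick"]), win.outcome_latency_s,
                    win.outcome_len_s),
    }
    rows = []
    for i, seg in enumerate(segments):
        row: dict[str, float] = {"trial": i, "valid": bool(segs.valid[i]),
                                 "baseline": segs.baselines[i]}
        for name, (times, latency, length) in anchors.items():
            t0 = times[i] + latency - starts[i]
            i0 = int(round(t0 * proc.fs))
            i1 = i0 + int(round(length * proc.fs))
            window = seg[max(0, i0): i1]
            if window.size == 0 or not segs.valid[i]:
                amp, lat = float("nan"), float("nan")
            elif method == "peak":
                amp, lat = detect_peak(window, fs=proc.fs)
            else:
                amp, lat = float(np.nanmean(window)), float("nan")
            row[f"{name}_amp"] = amp
            row[f"{name}_latency"] = lat
        rows.append(row)
    return pd.DataFrame(rows)
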