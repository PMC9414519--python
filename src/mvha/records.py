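"""Multichannel physiological records: data model, I/O, imputation, windowing.

A record bundles one or more high-frequency waveform channels (e.g. ECG at
125 Hz) with low-rate numeric vital-sign channels (e.g. HR, SpO2 at 1 Hz)
plus the timestamps of intervention events.  Around each event a 30-minute
pre-event extraction window is cut and split into a negative first half and
a positive second half; each half is then segmented into M equal 1-minute
pieces for the downstream model.

Conventions
-----------
Time is measured in seconds from record start.  A channel sampled at rate
``r`` stores sample ``i`` for the interval ``(i/r, (i+1)/r]``; the window
``(t-W, t]`` therefore maps to sample indices ``[r*(t-W), r*t)``.  Windows
are half-open on the left, segments likewise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

HIGH_FREQUENCY = "high_frequency"
NUMERIC = "numeric"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class ChannelSpec:
    """Identity and sampling geometry of one channel."""

    name: str
    kind: str  # HIGH_FREQUENCY or NUMERIC
    sampling_rate: float  # Hz

    def __post_init__(self):
        if self.kind not in (HIGH_FREQUENCY, NUMERIC):
            raise ValidationError(f"unknown channel kind {self.kind!r}")
        if not self.sampling_rate > 0:
            raise ValidationError(f"channel {self.name!r}: sampling_rate must be > 0")


@dataclass
class MultichannelRecord:
    """Raw per-channel series (NaN marks missing) plus event timestamps."""

    channels: list[ChannelSpec]
    series: list[np.ndarray]
    event_times: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.channels:
            raise ValidationError("record has no channels")
        if len(self.channels) != len(self.series):
            raise ValidationError("one series required per channel")
        self.series = [np.asarray(s, dtype=float) for s in self.series]
        durations = [len(s) / c.sampling_rate for c, s in zip(self.channels, self.series)]
        ref = durations[0]
        for c, d in zip(self.channels, durations):
            if abs(d - ref) > 1.0 / c.sampling_rate + 1e-9:
                raise ValidationError(
                    f"channel {c.name!r} spans {d:.3f}s but {self.channels[0].name!r} "
                    f"spans {ref:.3f}s (beyond one sample period)")
        hf_rates = [c.sampling_rate for c in self.channels if c.kind == HIGH_FREQUENCY]
        num_rates = [c.sampling_rate for c in self.channels if c.kind == NUMERIC]
        if hf_rates and num_rates and min(hf_rates) <= max(num_rates):
            raise ValidationError("high-frequency channels must sample faster than numeric ones")
        if list(self.event_times) != sorted(set(self.event_times)):
            raise ValidationError("event_times must be strictly increasing")
        for t in self.event_times:
            if not (0 < t <= ref + 1e-9):
                raise ValidationError(f"event time {t} outside record span (0, {ref}]")

    @property
    def duration(self) -> float:
        return len(self.series[0]) / self.channels[0].sampling_rate

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class LabeledWindow:
    """A W-second slice of every channel with a binary intervention label."""

    channels: list[ChannelSpec]
    series: list[np.ndarray]
    label: int
    source_event_time: float
    half: str  # "first" (label 0) or "second" (label 1)
    window_seconds: float

    def __post_init__(self):
        if (self.half == "first") != (self.label == 0):
            raise ValidationError("half=first must carry label 0, half=second label 1")
        for c, s in zip(self.channels, self.series):
            expect = int(round(self.window_seconds * c.sampling_rate))
            if len(s) != expect:
                raise ValidationError(
                    f"channel {c.name!r}: {len(s)} samples != W*rate = {expect}")


@dataclass
class SegmentedWindow:
    """A labeled window cut into M equal segments per channel.

    ``segments[name]`` is an (M, step_seconds*rate) array; concatenating its
    rows reproduces the window series exactly.
    """

    channels: list[ChannelSpec]
    segments: dict[str, np.ndarray]
    step_seconds: float
    label: int

    @property
    def n_segments(self) -> int:
        return next(iter(self.segments.values())).shape[0]


# --------------------------------------------------------------------- I/O

def read_record(manifest_path: str | Path) -> MultichannelRecord:
    """Read a record from a YAML manifest referencing per-channel CSV files.

    Manifest schema::

        channels:
          - {name: ECG, kind: high_frequency, sampling_rate: 125, path: ecg.csv}
          - {name: HR, kind: numeric, sampling_rate: 1, path: hr.csv}
        event_times: [1800.0]

    Channel CSVs have a ``time,value`` header; paths are resolved relative
    to the manifest.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not manifest or not manifest.get("channels"):
        raise ValidationError(f"manifest {manifest_path} lists no channels")
    channels, series = [], []
    for entry in manifest["channels"]:
        spec = ChannelSpec(name=str(entry["name"]), kind=entry["kind"],
                           sampling_rate=float(entry["sampling_rate"]))
        path = manifest_path.parent / entry["path"]
        if not path.exists():
            raise IOError(f"channel {spec.name!r}: file {path} not found")
        df = pd.read_csv(path)
        if not {"time", "value"}.issubset(df.columns):
            raise ValidationError(f"channel {spec.name!r}: expected columns time,value")
        channels.append(spec)
        series.append(df["value"].to_numpy(dtype=float))
    events = [float(t) for t in manifest.get("event_times", [])]
    return MultichannelRecord(channels=channels, series=series, event_times=events)


def write_windows(windows: list[LabeledWindow], out_dir: str | Path) -> Path:
    """Serialize windows as per-window CSVs plus a label index file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for i, w in enumerate(windows):
        wid = f"w{i:05d}"
        for c, s in zip(w.channels, w.series):
            pd.DataFrame({"time": np.arange(len(s)) / c.sampling_rate, "value": s}
                         ).to_csv(out_dir / f"{wid}_{c.name}.csv", index=False)
        index_rows.append({"window_id": wid, "label": w.label,
                           "event_time": w.source_event_time, "half": w.half})
    index_path = out_dir / "index.csv"
    pd.DataFrame(index_rows).to_csv(index_path, index=False)
    return index_path


# --------------------------------------------------------------- operations

def impute_missing(series: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Fill NaN entries by a piecewise cubic spline through observed points.

    Interior gaps are interpolated with a natural cubic spline; leading and
    trailing gaps are held at the nearest observed value (splines extrapolate
    wildly outside the data).  Observed values pass through unchanged.
    """
    series = np.asarray(series, dtype=float)
    observed = ~np.isnan(series)
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise ValidationError("cannot impute an all-missing series")
    if n_obs < 4:
        raise ValidationError(f"need >= 4 observed values for cubic imputation, got {n_obs}")
    if n_obs == len(series):
        return series.copy()
    idx = np.arange(len(series))
    obs_idx = idx[observed]
    spline = CubicSpline(obs_idx / sampling_rate, series[observed], bc_type="natural")
    out = series.copy()
    interior = ~observed & (idx > obs_idx[0]) & (idx < obs_idx[-1])
    out[interior] = spline(idx[interior] / sampling_rate)
    out[idx < obs_idx[0]] = series[obs_idx[0]]
    out[idx > obs_idx[-1]] = np.where(np.isnan(out[idx > obs_idx[-1]]),
                                      series[obs_idx[-1]], out[idx > obs_idx[-1]])
    return out


def extract_labeled_windows(record: MultichannelRecord,
                            pre_event_seconds: float = 1800.0
                            ) -> list[LabeledWindow]:
    """Cut a pre-event window around each isolated event and label its halves.

    For every event with full history and no other event inside its
    extraction window, emits two windows of W = pre_event_seconds/2: the
    first half labeled 0 (no impending intervention) and the second half —
    the span immediately preceding the event — labeled 1.  Events too close
    to the record start, or crowded by another event, are skipped with a
    warning.
    """
    windows: list[LabeledWindow] = []
    half_w = pre_event_seconds / 2.0
    for t_e in record.event_times:
        if t_e - pre_event_seconds < -1e-9:
            logger.warning("event at %.1fs skipped: insufficient history (< %.0fs)",
                           t_e, pre_event_seconds)
            continue
        others = [t for t in record.event_times
                  if t != t_e and t_e - pre_event_seconds < t <= t_e]
        if others:
            logger.warning("event at %.1fs skipped: other events in its window", t_e)
            continue
        halves = []
        ok = True
        for lo, hi in ((t_e - pre_event_seconds, t_e - half_w), (t_e - half_w, t_e)):
            chunk = []
            for c, s in zip(record.channels, record.series):
                i0 = int(round(c.sampling_rate * lo))
                i1 = int(round(c.sampling_rate * hi))
                if i0 < 0 or i1 > len(s):
                    ok = False
                    break
                chunk.append(s[i0:i1].copy())
            halves.append(chunk)
            if not ok:
                break
        if not ok:
            logger.warning("event at %.1fs skipped: window exceeds record span", t_e)
            continue
        windows.append(LabeledWindow(channels=list(record.channels), series=halves[0],
                                     label=0, source_event_time=t_e, half="first",
                                     window_seconds=half_w))
        windows.append(LabeledWindow(channels=list(record.channels), series=halves[1],
                                     label=1, source_event_time=t_e, half="second",
                                     window_seconds=half_w))
    return windows


def segment_window(window: LabeledWindow, step_seconds: float = 60.0) -> SegmentedWindow:
    """Split every channel of a window into M = W/step equal segments.

    The window length must be divisible by the step; silent truncation would
    change M and every downstream shape, so a remainder is a hard error.
    """
    ratio = window.window_seconds / step_seconds
    m = int(round(ratio))
    if abs(ratio - m) > 1e-9 or m < 1:
        raise ValidationError(
            f"window of {window.window_seconds}s not divisible by step {step_seconds}s")
    segments: dict[str, np.ndarray] = {}
    for c, s in zip(window.channels, window.series):
        per_seg = int(round(step_seconds * c.sampling_rate))
        if per_seg * m != len(s):
            raise ValidationError(
                f"channel {c.name!r}: {len(s)} samples not divisible into {m} segments")
        segments[c.name] = s.reshape(m, per_seg)
    return SegmentedWindow(channels=list(window.channels), segments=segments,
                           step_seconds=step_seconds, label=window.label)
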