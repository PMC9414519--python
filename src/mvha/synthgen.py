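"""Seeded generator of ICU-like multichannel records with known anomalies.

Each simulated intervention event yields a 30-minute record: the first
15 minutes are clean baseline (negative window), while the 15 minutes
immediately before the event (positive window) carry the configured
anomalies — localized variance bursts in chosen 1-minute segments (noise SD
multiplied by ``m_f``) and/or a sigmoid level shift of ``m_t`` × channel
range in one channel.  Ground-truth anomaly locations are returned so that
attention-recovery tests can check whether the model's α localizes the
bursts and β ranks the shifted channel first.

The baseline is a mean level plus a slow sinusoidal drift plus white noise;
the high-frequency channel additionally carries a periodic spike train as
an ECG stand-in.  No physiological realism is claimed beyond what makes the
knowledge features informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import (HIGH_FREQUENCY, NUMERIC, ChannelSpec, LabeledWindow,
                      MultichannelRecord, SegmentedWindow, ValidationError,
                      extract_labeled_windows, segment_window)


def default_channels() -> list[ChannelSpec]:
    return [
        ChannelSpec("ECG", HIGH_FREQUENCY, 125.0),
        ChannelSpec("HR", NUMERIC, 1.0),
        ChannelSpec("Pulse", NUMERIC, 1.0),
        ChannelSpec("Resp", NUMERIC, 1.0),
        ChannelSpec("SpO2", NUMERIC, 1.0),
    ]


#: per-channel (mean level, slow-drift amplitude, noise SD); ECG is a
#: zero-mean spike train (amplitude 1) riding on its noise floor.
DEFAULT_BASELINE: dict[str, tuple[float, float, float]] = {
    "ECG": (0.0, 0.0, 0.1),
    "HR": (80.0, 1.0, 2.0),
    "Pulse": (78.0, 1.0, 2.0),
    "Resp": (16.0, 0.5, 1.0),
    "SpO2": (97.0, 0.3, 0.6),
}


@dataclass
class SynthConfig:
    n_events: int = 50
    channels: list[ChannelSpec] = field(default_factory=default_channels)
    baseline: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE))
    pre_event_seconds: float = 1800.0
    step_seconds: float = 60.0
    fluct_segments: tuple[int, ...] = (11, 12, 13)  # 1-based, within positive window
    fluct_channels: tuple[str, ...] | None = None   # None = every channel
    fluct_multiplier: float = 4.0                   # m_f, SD multiplier > 1
    trend_channel: str | None = "HR"
    trend_fraction: float = 0.5                     # m_t, fraction of channel range
    missing_rate: float = 0.0
    drift_period: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if not self.fluct_multiplier > 1:
            raise ValidationError("fluct_multiplier m_f must exceed 1")
        if not 0 <= self.trend_fraction <= 1:
            raise ValidationError("trend_fraction m_t must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        m = int(round(self.pre_event_seconds / 2 / self.step_seconds))
        bad = [k for k in self.fluct_segments if not 1 <= k <= m]
        if bad:
            raise ValidationError(f"fluct segment indices {bad} outside 1..{m}")
        names = {c.name for c in self.channels}
        if self.trend_channel is not None and self.trend_channel not in names:
            raise ValidationError(f"trend_channel {self.trend_channel!r} not in channels")


@dataclass
class WindowTruth:
    label: int
    fluct_segments: tuple[int, ...]   # empty for negative windows
    fluct_channels: tuple[str, ...]
    trend_channel: str | None
    fluct_multiplier: float
    trend_fraction: float


@dataclass
class SynthTruth:
    config: SynthConfig
    windows: list[WindowTruth]


def _baseline_channel(cfg: SynthConfig, spec: ChannelSpec, n: int,
                      rng: np.random.Generator, phase: float) -> np.ndarray:
    mean, drift_amp, noise_sd = cfg.baseline.get(spec.name, (0.0, 0.0, 1.0))
    t = np.arange(n) / spec.sampling_rate
    sig = mean + drift_amp * np.sin(2 * np.pi * t / cfg.drift_period + phase)
    sig = sig + noise_sd * rng.standard_normal(n)
    if spec.kind == HIGH_FREQUENCY:
        # periodic spike train at ~72 bpm as a crude ECG stand-in
        beat = 60.0 / 72.0
        centers = np.arange(beat / 2, n / spec.sampling_rate, beat)
        width = 0.04
        for c in centers:
            lo = max(0, int((c - 4 * width) * spec.sampling_rate))
            hi = min(n, int((c + 4 * width) * spec.sampling_rate) + 1)
            sig[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    return sig


def _generate_event_record(cfg: SynthConfig, rng: np.random.Generator
                           ) -> MultichannelRecord:
    """One 30-min record ending at its (single) event, anomalies in the last half."""
    total = cfg.pre_event_seconds
    half = total / 2.0
    step = cfg.step_seconds
    noise_sd = {c.name: cfg.baseline.get(c.name, (0, 0, 1))[2] for c in cfg.channels}
    fluct_names = (tuple(c.name for c in cfg.channels)
                   if cfg.fluct_channels is None else cfg.fluct_channels)
    series = []
    for spec in cfg.channels:
        n = int(round(total * spec.sampling_rate))
        phase = rng.uniform(0, 2 * np.pi)
        sig = _baseline_channel(cfg, spec, n, rng, phase)
        t = np.arange(n) / spec.sampling_rate
        if spec.name in fluct_names and cfg.fluct_segments:
            extra = np.sqrt(cfg.fluct_multiplier ** 2 - 1.0) * noise_sd[spec.name]
            for k in cfg.fluct_segments:  # segment k of the positive half
                lo, hi = half + (k - 1) * step, half + k * step
                mask = (t >= lo) & (t < hi)
                sig[mask] += extra * rng.standard_normal(mask.sum())
        if spec.name == cfg.trend_channel and cfg.trend_fraction > 0:
            pos = t >= half
            rng_est = np.ptp(sig[pos])
            center, tau = half + half / 2.0, half / 20.0
            sig[pos] += (cfg.trend_fraction * rng_est
                         / (1.0 + np.exp(-(t[pos] - center) / tau)))
        if cfg.missing_rate > 0:
            miss = rng.random(n) < cfg.missing_rate
            sig[miss] = np.nan
        series.append(sig)
    return MultichannelRecord(channels=list(cfg.channels), series=series,
                              event_times=[total])


def generate_dataset(cfg: SynthConfig) -> tuple[list[LabeledWindow], SynthTruth]:
    """Generate ``n_events`` records and window them through the records pipeline.

    Returns one negative and one positive window per event (sibling pairs in
    adjacent positions) plus ground truth.  Windows may contain NaN entries
    when ``missing_rate`` > 0; impute before feature extraction.
    """
    rng = np.random.default_rng(cfg.seed)
    fluct_names = (tuple(c.name for c in cfg.channels)
                   if cfg.fluct_channels is None else cfg.fluct_channels)
    windows: list[LabeledWindow] = []
    truths: list[WindowTruth] = []
    for _ in range(cfg.n_events):
        record = _generate_event_record(cfg, rng)
        pair = extract_labeled_windows(record, cfg.pre_event_seconds)
        assert len(pair) == 2
        windows.extend(pair)
        truths.append(WindowTruth(0, (), (), None, cfg.fluct_multiplier,
                                  cfg.trend_fraction))
        truths.append(WindowTruth(1, tuple(cfg.fluct_segments), fluct_names,
                                  cfg.trend_channel, cfg.fluct_multiplier,
                                  cfg.trend_fraction))
    return windows, SynthTruth(config=cfg, windows=truths)


def generate_worked_example() -> tuple[SegmentedWindow, dict]:
    """Tiny fixed two-channel, three-segment window with hand-computed features.

    Channel A (1 Hz, 4 s segments): [1,3,1,3 | 5,5,5,5 | 2,4,6,8]
    Channel B: constant 7.
    """
    specs = [ChannelSpec("A", NUMERIC, 1.0), ChannelSpec("B", NUMERIC, 1.0)]
    a = np.array([1, 3, 1, 3, 5, 5, 5, 5, 2, 4, 6, 8], dtype=float)
    b = np.full(12, 7.0)
    window = LabeledWindow(channels=specs, series=[a, b], label=1,
                           source_event_time=12.0, half="second", window_seconds=12.0)
    seg = segment_window(window, step_seconds=4.0)
    expected = {
        # per-segment population SDs: SD([1,3,1,3])=1, SD(const)=0, SD([2,4,6,8])=sqrt(5)
        "fluct": np.array([[1.0, 0.0, np.sqrt(5.0)], [0.0, 0.0, 0.0]]),
        # channel A scaled by (x-1)/7 -> segment means 1/7, 4/7, 4/7 -> range 3/7
        "trend": np.array([3.0 / 7.0, 0.0]),
        # raw segment means 2, 5, 5 -> |diffs| 3, 0
        "diff_mean": np.array([[3.0, 0.0], [0.0, 0.0]]),
        # raw segment maxima 3, 5, 8 -> |diffs| 2, 3
        "diff_max": np.array([[2.0, 3.0], [0.0, 0.0]]),
    }
    return seg, expected
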