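"""Knowledge features driving the two attention mechanisms.

Two hand-computed statistics are injected into the attention scorers rather
than learned: the *fluctuant* feature — the population standard deviation of
each 1-minute segment, flagging localized variance bursts — and the *trend*
feature — the range of per-segment means after min–max scaling the whole
channel window, flagging monotone level shifts.  A third quantity, the
absolute difference of a segment statistic between consecutive segments,
enters the prediction head as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import SegmentedWindow, ValidationError

STATISTICS = {"max": np.max, "mean": np.mean, "min": np.min}


@dataclass
class FluctKnowledge:
    """Per-segment standard deviations; shape (CH, M), channel units."""

    channel_names: list[str]
    values: np.ndarray


@dataclass
class TrendKnowledge:
    """Per-channel trend range in [0, 1] (computed on min–max-scaled data)."""

    channel_names: list[str]
    values: np.ndarray


@dataclass
class TrendDiffs:
    """|ρ(s_{k+1}) − ρ(s_k)| per channel/statistic; each array (CH, M−1)."""

    channel_names: list[str]
    statistic_set: tuple[str, ...]
    values: dict[str, np.ndarray]

    def flatten(self) -> np.ndarray:
        """Covariate vector: statistics in declared order, channel-major."""
        return np.concatenate([self.values[st].reshape(-1) for st in self.statistic_set])


def segment_sd(segment: np.ndarray) -> float:
    """Population standard deviation sqrt(mean((s - s̄)²)) of one segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValidationError("segment_sd: empty segment")
    return float(np.std(segment))  # ddof=0: population form


def fluct_knowledge(window: SegmentedWindow) -> FluctKnowledge:
    """Stack per-segment SDs into the (CH, M) fluctuant feature matrix."""
    names = [c.name for c in window.channels]
    values = np.stack([np.std(window.segments[n], axis=1) for n in names])
    return FluctKnowledge(channel_names=names, values=values)


def minmax_scale(series: np.ndarray) -> np.ndarray:
    """Map a series affinely onto [0, 1]; a constant series maps to zeros."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValidationError("minmax_scale: empty series")
    lo, hi = series.min(), series.max()
    if hi == lo:
        return np.zeros_like(series)
    return (series - lo) / (hi - lo)


def trend_knowledge(window: SegmentedWindow) -> TrendKnowledge:
    """Per-channel range of scaled segment means.

    Each channel window is min–max scaled as a whole, segment means are
    taken on the scaled values, and the maximum absolute pairwise difference
    of those means — their range — is the channel's trend level.  A single
    segment (M = 1) or a constant channel yields 0.
    """
    names = [c.name for c in window.channels]
    out = np.empty(len(names))
    for i, n in enumerate(names):
        segs = window.segments[n]
        scaled = minmax_scale(segs.reshape(-1)).reshape(segs.shape)
        means = scaled.mean(axis=1)
        out[i] = float(means.max() - means.min())
    return TrendKnowledge(channel_names=names, values=out)


def segment_diffs(window: SegmentedWindow,
                  statistic_set: tuple[str, ...] = ("mean",)) -> TrendDiffs:
    """Absolute consecutive-segment differences of raw segment statistics."""
    if not statistic_set:
        raise ValidationError("segment_diffs: empty statistic_set")
    unknown = set(statistic_set) - set(STATISTICS)
    if unknown:
        raise ValidationError(f"segment_diffs: unknown statistics {sorted(unknown)}")
    names = [c.name for c in window.channels]
    if window.n_segments < 2:
        raise ValidationError("segment_diffs: need at least 2 segments")
    values = {}
    for st in statistic_set:
        fn = STATISTICS[st]
        rho = np.stack([fn(window.segments[n], axis=1) for n in names])  # (CH, M)
        values[st] = np.abs(np.diff(rho, axis=1))
    return TrendDiffs(channel_names=names, statistic_set=tuple(statistic_set),
                      values=values)


def feature_table(window_id: str, fluct: FluctKnowledge, trend: TrendKnowledge,
                  diffs: TrendDiffs | None = None) -> pd.DataFrame:
    """Long-form export of knowledge features for inspection."""
    rows = []
    for c, name in enumerate(fluct.channel_names):
        for k in range(fluct.values.shape[1]):
            rows.append({"window_id": window_id, "channel": name, "feature": "fluct_sd",
                         "k": k + 1, "value": fluct.values[c, k]})
        rows.append({"window_id": window_id, "channel": name, "feature": "trend_range",
                     "k": 0, "value": trend.values[c]})
        if diffs is not None:
            for st in diffs.statistic_set:
                for k in range(diffs.values[st].shape[1]):
                    rows.append({"window_id": window_id, "channel": name,
                                 "feature": f"diff_{st}", "k": k + 1,
                                 "value": diffs.values[st][c, k]})
    return pd.DataFrame(rows)
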