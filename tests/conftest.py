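import numpy as np
import pytest

from mvha.records import (HIGH_FREQUENCY, NUMERIC, ChannelSpec, LabeledWindow,
                          MultichannelRecord)
from mvha.synthgen import SynthConfig, generate_dataset, generate_worked_example


@pytest.fixture(scope="session")
def worked_example():
    """Tiny two-channel, three-segment window with hand-computed features."""
    return generate_worked_example()


@pytest.fixture
def five_channel_specs():
    return [ChannelSpec("ECG", HIGH_FREQUENCY, 125.0),
            ChannelSpec("HR", NUMERIC, 1.0),
            ChannelSpec("Pulse", NUMERIC, 1.0),
            ChannelSpec("Resp", NUMERIC, 1.0),
            ChannelSpec("SpO2", NUMERIC, 1.0)]


def make_record(event_times, duration=1800.0, rates=(125.0, 1.0), seed=0):
    rng = np.random.default_rng(seed)
    specs = [ChannelSpec("ECG", HIGH_FREQUENCY, rates[0]),
             ChannelSpec("HR", NUMERIC, rates[1])]
    series = [rng.normal(size=int(duration * s.sampling_rate)) for s in specs]
    return MultichannelRecord(channels=specs, series=series,
                              event_times=list(event_times))


def make_window(series_per_channel, rates=(1.0,), kinds=None, label=1,
                window_seconds=None):
    kinds = kinds or [NUMERIC] * len(series_per_channel)
    specs = [ChannelSpec(f"ch{i}", kinds[i], rates[i])
             for i in range(len(series_per_channel))]
    w = window_seconds or len(series_per_channel[0]) / rates[0]
    return LabeledWindow(channels=specs,
                         series=[np.asarray(s, float) for s in series_per_channel],
                         label=label, source_event_time=w,
                         half="second" if label else "first", window_seconds=w)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small reduced-rate synthetic dataset shared by pipeline tests."""
    cfg = SynthConfig(
        n_events=16,
        channels=[ChannelSpec("ECG", HIGH_FREQUENCY, 4.0),
                  ChannelSpec("HR", NUMERIC, 1.0),
                  ChannelSpec("SpO2", NUMERIC, 1.0)],
        missing_rate=0.005, seed=42)
    return generate_dataset(cfg)
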