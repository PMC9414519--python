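import numpy as np
import pytest
import yaml

from mvha.records import (HIGH_FREQUENCY, NUMERIC, ChannelSpec, MultichannelRecord,
                          ValidationError, extract_labeled_windows, impute_missing,
                          read_record, segment_window, write_windows)

from conftest import make_record, make_window


# ------------------------------------------------------------------ data model

def test_channel_spec_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        ChannelSpec("x", NUMERIC, -1.0)
    with pytest.raises(ValidationError):
        ChannelSpec("x", "weird_kind", 1.0)


def test_record_rejects_inconsistent_durations():
    specs = [ChannelSpec("a", NUMERIC, 1.0), ChannelSpec("b", NUMERIC, 1.0)]
    with pytest.raises(ValidationError, match="span"):
        MultichannelRecord(channels=specs,
                           series=[np.zeros(1800), np.zeros(1700)])


def test_record_requires_hf_faster_than_numeric():
    specs = [ChannelSpec("w", HIGH_FREQUENCY, 1.0), ChannelSpec("n", NUMERIC, 1.0)]
    with pytest.raises(ValidationError, match="faster"):
        MultichannelRecord(channels=specs, series=[np.zeros(100), np.zeros(100)])


# ------------------------------------------------------------------------ I/O

def _write_manifest(tmp_path, channels, events=(1800.0,), drop=None):
    entries = []
    for name, kind, rate, n in channels:
        path = tmp_path / f"{name.lower()}.csv"
        if name != drop:
            t = np.arange(n) / rate
            np.savetxt(path, np.c_[t, np.ones(n)], delimiter=",",
                       header="time,value", comments="")
        entries.append({"name": name, "kind": kind, "sampling_rate": rate,
                        "path": path.name})
    mpath = tmp_path / "manifest.yaml"
    mpath.write_text(yaml.safe_dump({"channels": entries,
                                     "event_times": list(events)}))
    return mpath


def test_read_record_roundtrip(tmp_path):
    mpath = _write_manifest(tmp_path, [("ECG", HIGH_FREQUENCY, 125.0, 225000),
                                       ("HR", NUMERIC, 1.0, 1800),
                                       ("Pulse", NUMERIC, 1.0, 1800),
                                       ("Resp", NUMERIC, 1.0, 1800),
                                       ("SpO2", NUMERIC, 1.0, 1800)])
    record = read_record(mpath)
    assert record.n_channels == 5
    assert record.channels[0].name == "ECG"
    assert record.event_times == [1800.0]
    assert len(record.series[0]) == 225000


def test_read_record_missing_file_names_channel(tmp_path):
    mpath = _write_manifest(tmp_path, [("ECG", HIGH_FREQUENCY, 10.0, 18000),
                                       ("HR", NUMERIC, 1.0, 1800)], drop="ECG")
    with pytest.raises(IOError, match="ECG"):
        read_record(mpath)


def test_read_record_inconsistent_spans(tmp_path):
    mpath = _write_manifest(tmp_path, [("ECG", HIGH_FREQUENCY, 10.0, 18000),
                                       ("HR", NUMERIC, 1.0, 1700)])
    with pytest.raises(ValidationError):
        read_record(mpath)


def test_read_record_empty_manifest(tmp_path):
    mpath = tmp_path / "m.yaml"
    mpath.write_text(yaml.safe_dump({"channels": []}))
    with pytest.raises(ValidationError):
        read_record(mpath)


def test_write_windows_roundtrip(tmp_path):
    w = make_window([np.arange(10.0)], rates=(1.0,), label=0)
    w.half, w.label = "first", 0
    index = write_windows([w], tmp_path / "out")
    import pandas as pd
    idx = pd.read_csv(index)
    assert list(idx.columns) == ["window_id", "label", "event_time", "half"]
    vals = pd.read_csv(tmp_path / "out" / "w00000_ch0.csv")["value"].to_numpy()
    np.testing.assert_array_equal(vals, np.arange(10.0))


# ------------------------------------------------------------------ imputation

def test_impute_identity_and_idempotence():
    s = np.sin(np.arange(20.0))
    out = impute_missing(s, 1.0)
    np.testing.assert_array_equal(out, s)


def test_impute_collinear_gap_recovers_line():
    # spline through collinear points is the line: missing t=2 fills with 2.0
    s = np.array([0.0, 1.0, np.nan, 3.0, 4.0])
    out = impute_missing(s, 1.0)
    assert out[2] == pytest.approx(2.0, abs=1e-9)
    np.testing.assert_array_equal(out[[0, 1, 3, 4]], [0, 1, 3, 4])


def test_impute_boundary_hold():
    s = np.array([np.nan, np.nan, 5.0, 6.0, 7.0, 8.0])
    out = impute_missing(s, 1.0)
    assert out[0] == 5.0 and out[1] == 5.0


def test_impute_requires_four_observations():
    with pytest.raises(ValidationError):
        impute_missing(np.array([1.0, np.nan, 2.0, 3.0]), 1.0)
    with pytest.raises(ValidationError):
        impute_missing(np.full(10, np.nan), 1.0)


# ------------------------------------------------------------------ windowing

def test_extract_halves_labels_and_lengths():
    record = make_record([1800.0], rates=(10.0, 1.0))
    wins = extract_labeled_windows(record, 1800.0)
    assert [w.label for w in wins] == [0, 1]
    assert [w.half for w in wins] == ["first", "second"]
    for w in wins:
        for c, s in zip(w.channels, w.series):
            assert len(s) == int(900 * c.sampling_rate)
    # the halves tile the original series
    np.testing.assert_array_equal(np.concatenate([wins[0].series[0],
                                                  wins[1].series[0]]),
                                  record.series[0])


def test_extract_skips_crowded_events():
    record = make_record([1750.0, 1800.0], duration=1800.0, rates=(10.0, 1.0))
    assert extract_labeled_windows(record, 1800.0) == []


def test_extract_skips_event_with_short_history():
    record = make_record([1000.0], duration=1800.0, rates=(10.0, 1.0))
    assert extract_labeled_windows(record, 1800.0) == []


def test_extract_balanced_classes():
    record = make_record([1800.0, 5400.0], duration=5400.0, rates=(10.0, 1.0))
    wins = extract_labeled_windows(record, 1800.0)
    labels = [w.label for w in wins]
    assert labels.count(0) == labels.count(1) == 2


# ---------------------------------------------------------------- segmentation

def test_segment_sample_counts_at_reference_rates():
    # 125 Hz / 60 s step -> 7500 samples; 1 Hz -> 60 values; M = 900/60 = 15
    rng = np.random.default_rng(0)
    w = make_window([rng.normal(size=112500), rng.normal(size=900)],
                    rates=(125.0, 1.0), kinds=[HIGH_FREQUENCY, NUMERIC])
    seg = segment_window(w, 60.0)
    assert seg.n_segments == 15
    assert seg.segments["ch0"].shape == (15, 7500)
    assert seg.segments["ch1"].shape == (15, 60)


def test_segment_round_trip_exact():
    rng = np.random.default_rng(1)
    w = make_window([rng.normal(size=1800), rng.normal(size=900)],
                    rates=(2.0, 1.0), kinds=[HIGH_FREQUENCY, NUMERIC])
    seg = segment_window(w, 60.0)
    for name, series in zip(("ch0", "ch1"), w.series):
        np.testing.assert_array_equal(seg.segments[name].reshape(-1), series)


def test_segment_rejects_non_divisible_step():
    w = make_window([np.zeros(900)], rates=(1.0,))
    with pytest.raises(ValidationError):
        segment_window(w, 7.0)
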