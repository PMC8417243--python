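"""Recording I/O, pre-ictal/inter-ictal labeling, and windowing."""

import numpy as np
import pytest

from seizgraph.eeg_io import (
    INTER_ICTAL,
    PRE_ICTAL,
    LabeledInterval,
    Recording,
    label_intervals,
    read_recording,
    segment_interval,
    select_channels,
    write_annotation_csv,
    write_edf,
    write_manifest,
)


def _rec(duration_s, fs=1.0, n_channels=1, onsets=(), offsets=(), **kw):
    return Recording(
        samples=np.zeros((n_channels, int(duration_s * fs))),
        sampling_rate=fs,
        channel_names=[f"C{i}" for i in range(n_channels)],
        seizure_onsets=list(onsets),
        seizure_offsets=list(offsets),
        **kw,
    )


class TestRecordingValidation:
    def test_onsets_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            _rec(100, onsets=[50, 20], offsets=[55, 25])

    def test_onset_beyond_duration(self):
        with pytest.raises(ValueError, match="beyond"):
            _rec(100, onsets=[150], offsets=[160])

    def test_channel_name_count(self):
        with pytest.raises(ValueError, match="channel names"):
            Recording(np.zeros((2, 10)), 1.0, ["only-one"])


class TestEdfRoundTrip:
    def test_write_then_read(self, tmp_path, rng):
        fs = 256
        t = np.arange(10 * fs) / fs
        samples = np.stack([
            50 * np.sin(2 * np.pi * 10 * t),
            20 * np.cos(2 * np.pi * 3 * t) + rng.normal(0, 5, size=len(t)),
        ])
        rec = Recording(samples, fs, ["FP1-F7", "F7-T7"], source_id="case01")
        edf = tmp_path / "case01.edf"
        write_edf(rec, edf)
        back = read_recording(edf)
        assert back.duration == pytest.approx(10.0)
        assert back.n_samples == 2560
        assert back.sampling_rate == 256
        assert back.channel_names == ["FP1-F7", "F7-T7"]
        # 16-bit quantization over a ~±60 µV range: tolerance well below 0.1 µV
        assert np.max(np.abs(back.samples - rec.samples)) < 0.05

    def test_csv_annotations_roundtrip(self, tmp_path):
        fs = 64
        rec = Recording(np.zeros((1, 100 * fs)), fs, ["C0"],
                        seizure_onsets=[40.0], seizure_offsets=[50.0],
                        source_id="case02")
        edf, csv_path = tmp_path / "case02.edf", tmp_path / "case02.csv"
        write_edf(rec, edf)
        write_annotation_csv(rec, csv_path)
        back = read_recording(edf, csv_path)
        assert back.seizure_onsets == [40.0]
        assert back.seizure_offsets == [50.0]

    def test_summary_annotations(self, tmp_path):
        fs = 64
        rec = _rec(100, fs=fs)
        edf = tmp_path / "chb01_03.edf"
        write_edf(rec, edf)
        summary = tmp_path / "chb01-summary.txt"
        summary.write_text(
            "File Name: chb01_02.edf\nNumber of Seizures in File: 0\n\n"
            "File Name: chb01_03.edf\n"
            "Seizure Start Time: 30 seconds\n"
            "Seizure End Time: 45 seconds\n"
        )
        back = read_recording(edf, summary)
        assert back.seizure_onsets == [30.0]
        assert back.seizure_offsets == [45.0]

    def test_out_of_range_annotation_rejected(self, tmp_path):
        fs = 64
        rec = _rec(100, fs=fs, source_id="caseX")
        edf, csv_path = tmp_path / "caseX.edf", tmp_path / "caseX.csv"
        write_edf(rec, edf)
        csv_path.write_text("case,onset_s,offset_s\ncaseX,7200,7230\n")
        with pytest.raises(ValueError, match="exceeds"):
            read_recording(edf, csv_path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.edf"):
            read_recording(tmp_path / "nope.edf")


class TestSelectChannels:
    def test_permutation(self):
        rec = Recording(np.arange(12.0).reshape(3, 4), 1.0, ["A", "B", "C"])
        out = select_channels(rec, ["C", "A"])
        assert out.channel_names == ["C", "A"]
        np.testing.assert_array_equal(out.samples[0], rec.samples[2])
        np.testing.assert_array_equal(out.samples[1], rec.samples[0])

    def test_case_and_whitespace_insensitive(self):
        rec = Recording(np.zeros((2, 4)), 1.0, ["FP1-F7", "F7 - T7"])
        out = select_channels(rec, ["fp1-f7", "F7-T7"])
        assert out.n_channels == 2

    def test_missing_label_named(self):
        rec = Recording(np.zeros((2, 4)), 1.0, ["A", "B"])
        with pytest.raises(KeyError, match="XX"):
            select_channels(rec, ["A", "XX"])


class TestLabelIntervals:
    def test_single_onset_standard_rule(self):
        rec = _rec(7500, onsets=[7200], offsets=[7230])
        pre = [iv for iv in label_intervals(rec) if iv.label == PRE_ICTAL]
        assert len(pre) == 1
        assert (pre[0].start, pre[0].end) == (3600.0, 6900.0)

    def test_no_seizures_whole_recording_interictal(self):
        rec = _rec(5000)
        ivs = label_intervals(rec)
        assert [iv.label for iv in ivs] == [INTER_ICTAL]
        assert (ivs[0].start, ivs[0].end) == (0.0, 5000.0)

    def test_truncation_by_prior_seizure(self):
        rec = _rec(6000, onsets=[4000, 5000], offsets=[4100, 5040])
        pre = [iv for iv in label_intervals(rec) if iv.label == PRE_ICTAL]
        assert (pre[0].start, pre[0].end) == (400.0, 3700.0)
        assert (pre[1].start, pre[1].end) == (4100.0, 4700.0)

    def test_onset_too_early_skipped_with_warning(self, caplog):
        rec = _rec(5000, onsets=[200], offsets=[230])
        with caplog.at_level("WARNING"):
            pre = [iv for iv in label_intervals(rec) if iv.label == PRE_ICTAL]
        assert pre == []
        assert any("skipped" in r.message for r in caplog.records)

    def test_labels_never_overlap_even_with_small_guard(self):
        rec = _rec(30000, onsets=[10000, 20000], offsets=[10060, 20100])
        ivs = label_intervals(rec, inter_guard=600.0)
        ivs = sorted(ivs, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end <= b.start + 1e-12

    def test_deterministic(self):
        rec = _rec(30000, onsets=[9000, 21000], offsets=[9050, 21050])
        assert label_intervals(rec) == label_intervals(rec)

    def test_bad_offsets_rejected(self):
        rec = _rec(7500, onsets=[7200], offsets=[7230])
        with pytest.raises(ValueError):
            label_intervals(rec, pre_start_offset=100.0, pre_end_offset=300.0)


class TestSegmentInterval:
    @pytest.mark.parametrize(
        "length,window,overlap,expected",
        [
            (3300, 5.0, 0.5, 1319),  # floor((3300-5)/2.5) + 1
            (3300, 5.0, 0.0, 660),   # floor(3300/5)
            (4, 5.0, 0.0, 0),        # shorter than one window
        ],
    )
    def test_window_counts(self, length, window, overlap, expected):
        rec = _rec(3300, fs=2.0)
        iv = LabeledInterval(0.0, float(length), PRE_ICTAL)
        segs = segment_interval(rec, iv, window, overlap)
        assert len(segs) == expected

    def test_overlap_doubles_segment_count(self):
        rec = _rec(200, fs=2.0)
        iv = LabeledInterval(0.0, 200.0, PRE_ICTAL)
        n0 = len(segment_interval(rec, iv, 5.0, 0.0))
        n50 = len(segment_interval(rec, iv, 5.0, 0.5))
        assert abs(n50 - 2 * n0) <= 1

    def test_segments_stay_inside_interval(self):
        rec = _rec(103, fs=4.0)
        iv = LabeledInterval(7.0, 103.0, INTER_ICTAL)
        for seg in segment_interval(rec, iv, 5.0, 0.5):
            assert seg.start_time >= iv.start
            assert seg.start_time + 5.0 <= iv.end + 1e-9
            assert seg.window_samples == 20

    def test_label_and_metadata_carried(self):
        rec = _rec(50, fs=2.0, source_id="caseZ")
        iv = LabeledInterval(10.0, 30.0, PRE_ICTAL)
        segs = segment_interval(rec, iv, 5.0, 0.0)
        assert all(s.label == PRE_ICTAL and s.source_id == "caseZ" for s in segs)

    def test_invalid_overlap(self):
        rec = _rec(50, fs=2.0)
        iv = LabeledInterval(0.0, 50.0, PRE_ICTAL)
        with pytest.raises(ValueError):
            segment_interval(rec, iv, 5.0, 1.0)


def test_manifest_csv(tmp_path):
    rec = _rec(50, fs=2.0, source_id="m1")
    iv = LabeledInterval(0.0, 20.0, INTER_ICTAL)
    segs = segment_interval(rec, iv, 5.0, 0.0)
    path = tmp_path / "manifest.csv"
    write_manifest(segs, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "source_id,start_time,label"
    assert len(lines) == 1 + len(segs)
    assert lines[1].startswith("m1,0.000,inter_ictal")
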