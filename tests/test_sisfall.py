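import numpy as np
import pytest

import fallkit as fk
from fallkit import sisfall
from fallkit.errors import ConfigurationError, TraceParseError, TraceTooShortError


def write_rows(path, rows):
    path.write_text("\n".join(",".join(str(c) for c in row) + ";" for row in rows) + "\n")


class TestReadTrace:
    def test_counts_to_g_conversion(self, tmp_path):
        path = tmp_path / "D01_SA01_R01.txt"
        write_rows(path, [(0, 0, 256)] * 3)
        trace = fk.read_trace(path)
        assert len(trace) == 3
        assert np.allclose(trace.magnitude_series().values, 1.0)
        assert trace.subject_id == "SA01"
        assert trace.activity_code == "D01"
        assert not trace.is_fall

    def test_fall_flag_from_filename(self, tmp_path):
        path = tmp_path / "F05_SA02_R02.txt"
        write_rows(path, [(0, 0, 256)] * 2)
        assert fk.read_trace(path).is_fall

    def test_extra_columns_are_ignored(self, tmp_path):
        base = tmp_path / "D01_SA01_R01.txt"
        wide = tmp_path / "D01_SA01_R02.txt"
        write_rows(base, [(10, -20, 250)] * 4)
        write_rows(wide, [(10, -20, 250, 7, 8, 9, 1, 2, 3)] * 4)
        a, b = fk.read_trace(base), fk.read_trace(wide)
        assert np.array_equal(a.ax, b.ax)
        assert np.array_equal(a.ay, b.ay)
        assert np.array_equal(a.az, b.az)

    def test_parse_error_names_the_line(self, tmp_path):
        path = tmp_path / "D01_SA01_R01.txt"
        path.write_text("1,2,3;\n1,x,3;\n")
        with pytest.raises(TraceParseError, match=":2:"):
            fk.read_trace(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            fk.read_trace(tmp_path / "F01_SA01_R01.txt")


def make_trace(mag_profile, fs=200.0, **kwargs):
    """Trace whose z-axis carries a prescribed magnitude profile."""
    mag = np.asarray(mag_profile, dtype=float)
    return fk.AccelTrace(
        ax=np.zeros_like(mag), ay=np.zeros_like(mag), az=mag, fs=fs, **kwargs
    )


class TestFallWindowExtraction:
    def test_window_centered_on_global_peak(self):
        mag = np.ones(2000)
        mag[1000] = 6.0  # impact at t = 5 s
        pattern = fk.extract_fall_window(make_trace(mag, is_fall=True))
        assert pattern.values.shape == (80,)
        assert pattern.label == 1
        assert pattern.values.max() == pytest.approx(6.0)
        assert pattern.values.argmax() == 40

    def test_peak_near_start_clamps_window(self):
        mag = np.ones(2000)
        mag[100] = 5.0  # within 2 s of the start
        pattern = fk.extract_fall_window(make_trace(mag, is_fall=True))
        assert pattern.values.shape == (80,)
        assert pattern.values.max() == pytest.approx(5.0)
        assert pattern.values.argmax() == 10  # clamped to [0, 4 s]

    def test_tie_breaks_to_earliest_peak(self):
        mag = np.ones(4000)
        mag[900] = 5.0
        mag[3000] = 5.0
        a = fk.extract_fall_window(make_trace(mag, is_fall=True))
        b = fk.extract_fall_window(make_trace(mag, is_fall=True))
        assert a.meta["center_index"] == 900
        assert np.array_equal(a.values, b.values)

    def test_too_short_trace_raises(self):
        with pytest.raises(TraceTooShortError):
            fk.extract_fall_window(make_trace(np.ones(700), is_fall=True))

    def test_window_preserves_the_native_peak(self):
        # the decimation grid of the extracted window is phase-aligned to the
        # peak sample, so the native global maximum survives decimation
        trace = fk.generate_fall_trace(fk.SyntheticConfig(), "SY01", "forward", seed=3)
        pattern = fk.extract_fall_window(trace)
        native_max = trace.magnitude_series().values.max()
        assert pattern.values.max() == pytest.approx(native_max)


class TestAdlWindowExtraction:
    def test_three_nonoverlapping_windows_from_long_trace(self):
        t = np.arange(12000) / 200.0  # 60 s walking-like signal
        mag = 1.0 + 0.4 * np.sin(2 * np.pi * 2.0 * t)
        patterns = fk.extract_adl_windows(make_trace(mag))
        assert len(patterns) == 3
        centers = sorted(p.meta["center_index"] for p in patterns)
        assert all(b - a >= 4 * 200 for a, b in zip(centers, centers[1:]))
        assert all(p.label == 0 for p in patterns)

    def test_short_trace_yields_single_window(self):
        t = np.arange(1000) / 200.0  # 5 s
        mag = 1.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t)
        assert len(fk.extract_adl_windows(make_trace(mag))) == 1

    def test_supra_threshold_spike_ranks_first(self):
        t = np.arange(4000) / 200.0
        mag = 1.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t)
        mag[2400] = 3.2
        patterns = fk.extract_adl_windows(make_trace(mag))
        tallest = max(patterns, key=lambda p: p.values.max())
        assert tallest.meta["center_index"] == 2400


class TestPartition:
    def test_explicit_split_counts(self, small_patterns):
        subjects = sorted({p.subject_id for p in small_patterns})
        split = fk.SplitSpec(
            train_subjects=tuple(subjects[:3]),
            val_subjects=tuple(subjects[3:4]),
            test_subjects=tuple(subjects[4:]),
        )
        train, val, test = fk.partition_by_subject(small_patterns, split, expected_subjects=5)
        assert len(train) + len(val) + len(test) == len(small_patterns)
        assert {p.subject_id for p in train} == set(subjects[:3])

    def test_no_subject_leakage(self, small_patterns):
        train, val, test = fk.partition_by_subject(small_patterns, 5, expected_subjects=5)
        groups = [{p.subject_id for p in part} for part in (train, val, test)]
        assert not (groups[0] & groups[1])
        assert not (groups[0] & groups[2])
        assert not (groups[1] & groups[2])

    def test_seeded_partition_is_deterministic(self, small_patterns):
        a = fk.partition_by_subject(small_patterns, 5, expected_subjects=5)
        b = fk.partition_by_subject(small_patterns, 5, expected_subjects=5)
        for pa, pb in zip(a, b):
            assert [p.subject_id for p in pa] == [p.subject_id for p in pb]

    def test_ten_subjects_cut_6_2_2(self):
        split = fk.make_split([f"S{i}" for i in range(10)], seed=0)
        assert (len(split.train_subjects), len(split.val_subjects), len(split.test_subjects)) == (6, 2, 2)

    def test_subject_count_mismatch_raises(self, small_patterns):
        with pytest.raises(ConfigurationError):
            fk.partition_by_subject(small_patterns, 5, expected_subjects=10)


class TestPipelineComposition:
    def test_manual_signal_ops_reproduce_fall_pattern(self):
        trace = fk.generate_fall_trace(fk.SyntheticConfig(), "SY02", "lateral", seed=9)
        pattern = fk.extract_fall_window(trace)
        # manual route: native magnitude peak -> 800-sample slice -> decimate -> magnitude
        mag = trace.magnitude_series().values
        peak = int(np.argmax(mag))
        start = min(max(peak - 400, 0), len(trace) - 800)
        manual = fk.magnitude(
            trace.ax[start : start + 800][::10],
            trace.ay[start : start + 800][::10],
            trace.az[start : start + 800][::10],
        )
        assert np.array_equal(pattern.values, manual)

    def test_every_trace_contributes_expected_patterns(self, small_traces, small_patterns):
        n_falls = sum(t.is_fall for t in small_traces)
        fall_patterns = [p for p in small_patterns if p.label == 1]
        assert len(fall_patterns) == n_falls
        adl_patterns = [p for p in small_patterns if p.label == 0]
        n_adls = sum(not t.is_fall for t in small_traces)
        assert n_adls <= len(adl_patterns) <= 3 * n_adls

    def test_roundtrip_through_dataframe(self, small_patterns):
        df = sisfall.patterns_to_dataframe(small_patterns[:5])
        back = sisfall.dataframe_to_patterns(df)
        for a, b in zip(small_patterns[:5], back):
            assert np.allclose(a.values, b.values)
            assert a.label == b.label
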