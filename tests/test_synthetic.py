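import json

import numpy as np
import pytest

import fallkit as fk
from fallkit.errors import ConfigurationError


def at_20hz(trace):
    return fk.downsample(trace, int(round(trace.fs / 20.0))).magnitude_series()


class TestFallTraces:
    @pytest.mark.parametrize("fall_type", fk.FALL_TYPES)
    def test_every_fall_triggers_the_detector(self, fall_type):
        config = fk.SyntheticConfig()
        for seed in range(5):
            trace = fk.generate_fall_trace(config, "SY01", fall_type, seed=seed)
            windows = fk.detect_events_offline(at_20hz(trace))
            assert len(windows) >= 1
            assert trace.is_fall

    def test_peak_magnitude_within_configured_range(self):
        config = fk.SyntheticConfig()
        lo, hi = config.fall_impact_peak_g
        tol = 4 * config.noise_sd_g
        for seed in range(200):
            trace = fk.generate_fall_trace(config, "SY01", "forward", seed=seed)
            peak = trace.magnitude_series().values.max()
            assert lo - tol <= peak <= hi + tol

    def test_freefall_dip_precedes_impact(self):
        config = fk.SyntheticConfig()
        trace = fk.generate_fall_trace(config, "SY01", "backward_supine", seed=2)
        mag = trace.magnitude_series().values
        impact = int(np.argmax(mag))
        pre = mag[max(0, impact - int(0.6 * trace.fs)) : impact]
        assert pre.min() < 0.7  # the free-fall signature

    def test_orientation_changes_after_impact(self):
        config = fk.SyntheticConfig()
        trace = fk.generate_fall_trace(config, "SY01", "lateral", seed=3)
        n = len(trace)
        early = np.array([trace.ax[: n // 8].mean(), trace.ay[: n // 8].mean(), trace.az[: n // 8].mean()])
        late = np.array([trace.ax[-n // 8 :].mean(), trace.ay[-n // 8 :].mean(), trace.az[-n // 8 :].mean()])
        cos = early @ late / (np.linalg.norm(early) * np.linalg.norm(late))
        assert cos < 0.9  # resting orientation differs from standing

    def test_same_seed_is_bit_identical(self):
        config = fk.SyntheticConfig()
        a = fk.generate_fall_trace(config, "SY01", "forward", seed=7)
        b = fk.generate_fall_trace(config, "SY01", "forward", seed=7)
        assert np.array_equal(a.ax, b.ax) and np.array_equal(a.az, b.az)

    def test_unknown_fall_type_rejected(self):
        with pytest.raises(ConfigurationError):
            fk.generate_fall_trace(fk.SyntheticConfig(), "SY01", "tumble", seed=0)


class TestAdlTraces:
    @pytest.mark.parametrize("adl_type", fk.ADL_TYPES)
    def test_non_distractor_adls_never_trigger(self, adl_type):
        config = fk.SyntheticConfig()
        for seed in range(10):
            trace = fk.generate_adl_trace(
                config, "SY01", adl_type, seed=seed, force_distractor=False
            )
            assert trace.magnitude_series().values.max() < 3.0
            assert fk.detect_events_offline(at_20hz(trace)) == []

    def test_distractors_trigger_but_lack_freefall_dip(self):
        config = fk.SyntheticConfig()
        for seed in range(10):
            trace = fk.generate_adl_trace(
                config, "SY01", "walk", seed=seed, force_distractor=True
            )
            windows = fk.detect_events_offline(at_20hz(trace))
            assert len(windows) >= 1
            mag = trace.magnitude_series().values
            impact = int(np.argmax(mag))
            pre = mag[max(0, impact - int(0.6 * trace.fs)) : impact]
            assert pre.min() > 0.4  # no free-fall phase before the spike
            assert not trace.is_fall

    def test_distractor_frequency_matches_probability(self):
        config = fk.SyntheticConfig(distractor_prob=0.2)
        n = 600
        hits = sum(
            fk.generate_adl_trace(config, "SY01", "walk", seed=s).meta["distractor"]
            for s in range(n)
        )
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(hits / n - 0.2) < 3 * se

    def test_unknown_adl_type_rejected(self):
        with pytest.raises(ConfigurationError):
            fk.generate_adl_trace(fk.SyntheticConfig(), "SY01", "juggle", seed=0)


class TestDataset:
    def test_default_corpus_shape(self, small_config, small_traces):
        per_subject = small_config.falls_per_subject + small_config.adls_per_subject
        assert len(small_traces) == small_config.n_subjects * per_subject
        by_subject = {}
        for t in small_traces:
            by_subject.setdefault(t.subject_id, []).append(t)
        for subject_traces in by_subject.values():
            falls = sum(t.is_fall for t in subject_traces)
            assert falls == small_config.falls_per_subject

    def test_same_seed_identical_manifest_different_seed_differs(self, small_config):
        _, m1 = fk.generate_dataset(small_config)
        _, m2 = fk.generate_dataset(small_config)
        assert m1 == m2
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        traces_a, _ = fk.generate_dataset(small_config)
        traces_b, _ = fk.generate_dataset(other)
        assert not np.array_equal(traces_a[0].ax, traces_b[0].ax)

    def test_roundtrip_through_sisfall_csv(self, tmp_path):
        config = fk.SyntheticConfig(seed=4, n_subjects=4, falls_per_subject=1, adls_per_subject=1)
        traces, manifest = fk.generate_dataset(config, out_dir=tmp_path)
        assert (tmp_path / "manifest.json").exists()
        loaded = json.loads((tmp_path / "manifest.json").read_text())
        assert len(loaded) == len(traces)
        from fallkit.sisfall import read_dataset

        back = read_dataset(tmp_path, manifest=loaded)
        quantum = 1.0 / 256.0
        for orig, rt in zip(traces, back):
            assert rt.subject_id == orig.subject_id
            assert rt.is_fall == orig.is_fall
            mag_err = np.abs(
                rt.magnitude_series().values - orig.magnitude_series().values
            ).max()
            assert mag_err < quantum * np.sqrt(3)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            fk.generate_dataset(fk.SyntheticConfig(n_subjects=3))
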