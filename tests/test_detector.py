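import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fallkit as fk
from fallkit.detector import DetectorConfig
from fallkit.errors import InvalidInputError, ReassemblyError
from fallkit.signals import MagnitudeSeries


def stream(values, config=None):
    return fk.StreamingDetector(config).process(values)


def offline(values, config=None):
    return fk.detect_events_offline(MagnitudeSeries(np.asarray(values, float), 20.0), config)


class TestStreamingDetector:
    def test_subthreshold_stream_never_emits(self):
        assert stream([1.0] * 500) == []

    def test_single_trigger_emits_one_80_sample_window(self):
        values = [1.0] * 100 + [3.5] + [1.0] * 60
        windows = stream(values)
        assert len(windows) == 1
        w = windows[0]
        assert len(w) == 80
        assert w.trigger_index == 40
        assert w.values.max() == pytest.approx(3.5)
        assert w.values[40] == pytest.approx(3.5)

    def test_cold_start_pads_with_earliest_sample(self):
        # trigger at position 10: only 10 samples of history exist
        values = [0.8] * 10 + [3.2] + [1.0] * 50
        windows = stream(values)
        assert len(windows) == 1
        w = windows[0]
        assert len(w) == 80
        assert np.allclose(w.values[:40], 0.8)  # padded + real history
        assert w.values[40] == pytest.approx(3.2)

    def test_exactly_at_threshold_does_not_trigger(self):
        assert stream([1.0] * 50 + [3.0] + [1.0] * 50) == []

    def test_incomplete_capture_at_stream_end_emits_nothing(self):
        assert stream([1.0] * 50 + [3.5] + [1.0] * 10) == []

    def test_crossings_during_capture_do_not_retrigger(self):
        values = [1.0] * 50 + [3.5] + [1.0] * 20 + [3.6] + [1.0] * 60
        windows = stream(values)
        assert len(windows) == 1
        assert windows[0].trigger_value == pytest.approx(3.5)

    def test_buffer_resets_after_emission(self):
        # second event right after the first window: its pre-history may only
        # contain post-reset samples, so the early 9.0 marker must not appear
        values = [9.0] * 0 + [2.0] * 50 + [3.5] + [2.0] * 39 + [1.5] * 10 + [3.7] + [1.5] * 39
        windows = stream(values)
        assert len(windows) == 2
        second = windows[1]
        assert 2.0 not in second.values  # pre-reset samples are gone
        assert np.allclose(second.values[:40], 1.5)


class TestOfflineOracleEquivalence:
    def test_no_crossing_gives_empty_list(self):
        assert offline(np.full(200, 1.0)) == []

    def test_close_crossings_yield_one_window(self):
        values = np.concatenate([np.ones(60), [3.5], np.ones(29), [3.8], np.ones(60)])
        windows = offline(values)
        assert len(windows) == 1

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_streaming_equals_offline(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 400))
        values = rng.uniform(0.0, 4.5, size=n)
        ws = stream(values)
        wo = offline(values)
        assert len(ws) == len(wo)
        for a, b in zip(ws, wo):
            assert np.array_equal(a.values, b.values)
            assert a.trigger_index == b.trigger_index
            assert a.trigger_value == b.trigger_value

    def test_every_window_contains_its_trigger(self, rng):
        for _ in range(50):
            values = rng.uniform(0.5, 4.5, size=300)
            for w in offline(values):
                assert len(w) == 80
                assert w.values[w.trigger_index] > 3.0


class TestLinkSimulation:
    @pytest.fixture()
    def window(self):
        values = np.concatenate([np.ones(40), [3.5], np.ones(39)])
        return fk.EventWindow(values=values, trigger_index=40)

    def test_lossless_link_delivers_everything_first_try(self, window):
        packets = fk.simulate_link(window, loss_prob=0.0, seed=0)
        assert len(packets) == 4
        assert all(p.attempts == 1 for p in packets)

    def test_single_packet_mode(self, window):
        packets = fk.simulate_link(window, samples_per_packet=80, loss_prob=0.0, seed=0)
        assert len(packets) == 1
        assert packets[0].payload.size == 80

    def test_delivery_rate_matches_bernoulli_compounding(self, window):
        # with loss p = 0.5 and 3 retransmissions: P(delivered) = 1 - 0.5^4
        delivered = 0
        total = 0
        for seed in range(2500):  # 2500 windows x 4 packets = 10000 packets
            packets = fk.simulate_link(window, loss_prob=0.5, max_retransmissions=3, seed=seed)
            delivered += len(packets)
            total += 4
        rate = delivered / total
        assert rate == pytest.approx(1 - 0.5**4, abs=0.01)

    def test_deterministic_given_seed(self, window):
        a = fk.simulate_link(window, loss_prob=0.3, seed=99)
        b = fk.simulate_link(window, loss_prob=0.3, seed=99)
        assert [(p.seq, p.attempts) for p in a] == [(p.seq, p.attempts) for p in b]

    def test_rejects_certain_loss(self, window):
        with pytest.raises(InvalidInputError):
            fk.simulate_link(window, loss_prob=1.0, seed=0)


class TestGatewayReassembly:
    def window(self):
        values = np.arange(80.0)
        return fk.EventWindow(values=values, trigger_index=40)

    def test_all_packets_present_is_identity(self):
        w = self.window()
        packets = fk.simulate_link(w, loss_prob=0.0, seed=0)
        out = fk.gateway_reassemble(packets)
        assert np.array_equal(out.values, w.values)
        assert out.origin == "reassembled"

    def test_middle_gap_filled_with_last_valid_sample(self):
        w = self.window()
        packets = fk.simulate_link(w, samples_per_packet=27, loss_prob=0.0, seed=0)
        kept = [p for p in packets if p.seq != 1]
        out = fk.gateway_reassemble(kept)
        assert np.allclose(out.values[27:54], w.values[26])  # LOCF across the gap
        assert np.array_equal(out.values[:27], w.values[:27])
        assert np.array_equal(out.values[54:], w.values[54:])

    def test_missing_prefix_filled_with_first_valid_sample(self):
        w = self.window()
        packets = [p for p in fk.simulate_link(w, loss_prob=0.0, seed=0) if p.seq != 0]
        out = fk.gateway_reassemble(packets)
        assert np.allclose(out.values[:20], w.values[20])
        assert len(out) == 80
        assert not np.isnan(out.values).any()

    def test_zero_packets_is_a_lost_event(self):
        with pytest.raises(ReassemblyError):
            fk.gateway_reassemble([])

    def test_windows_complete_under_ten_percent_loss(self):
        w = self.window()
        for seed in range(200):
            packets = fk.simulate_link(w, loss_prob=0.10, max_retransmissions=3, seed=seed)
            out = fk.gateway_reassemble(packets)
            assert len(out) == 80
            assert not np.isnan(out.values).any()


class TestDetectorConfig:
    def test_default_ring_capacity_is_40(self):
        config = DetectorConfig()
        assert config.pre_samples == 40
        assert config.post_samples == 40
        assert config.window_samples == 80

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(InvalidInputError):
            DetectorConfig(threshold=0.0)
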