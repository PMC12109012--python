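"""Sensor-node pre-detector, lossy-link simulation, and gateway reassembly.

The wearable node samples the acceleration magnitude at 20 Hz into a 2-s
circular buffer. Whenever a sample *exceeds* 3 g — the impact signature every
fall carries — the node captures a further 2 s and emits a 4-s, 80-sample
event window (40 buffered pre-trigger samples, the trigger at index 40, and 39
post-trigger samples), then resets the buffer and resumes monitoring. Sub-3 g
activity never leaves the device, which is what makes the duty-cycled radio
budget work.

The link layer is modelled as independent per-packet Bernoulli loss with a
bounded number of retransmissions; the gateway rebuilds a complete 80-sample
window from whatever packets arrived by carrying the last valid sample forward
across gaps (LOCF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import InvalidInputError, ReassemblyError
from .signals import MagnitudeSeries

FALL_THRESHOLD_G = 3.0


@dataclass(frozen=True)
class DetectorConfig:
    fs: float = 20.0
    buffer_seconds: float = 2.0
    post_seconds: float = 2.0
    threshold: float = FALL_THRESHOLD_G
    refractory_seconds: float = 0.0

    def __post_init__(self):
        if self.threshold <= 0:
            raise InvalidInputError("threshold must be positive")
        for name in ("pre_samples", "post_samples"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be a positive integer")

    @property
    def pre_samples(self) -> int:
        return int(round(self.fs * self.buffer_seconds))

    @property
    def post_samples(self) -> int:
        """Samples captured from the trigger on (trigger included)."""
        return int(round(self.fs * self.post_seconds))

    @property
    def window_samples(self) -> int:
        return self.pre_samples + self.post_samples

    @property
    def refractory_samples(self) -> int:
        return int(round(self.fs * self.refractory_seconds))


@dataclass(frozen=True)
class EventWindow:
    """One 80-sample (4 s at 20 Hz) magnitude window around a trigger."""

    values: np.ndarray
    trigger_index: int
    origin: str = "streamed"  # streamed | reassembled | dataset | synthetic
    trigger_value: float = float("nan")

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise InvalidInputError("window values must be one-dimensional")
        if not 0 <= self.trigger_index < self.values.size:
            raise InvalidInputError("trigger_index outside window")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DetectorState:
    """Mutable node state: ring buffer plus capture bookkeeping."""

    ring: List[float] = field(default_factory=list)
    mode: str = "monitoring"  # monitoring | capturing
    capture: List[float] = field(default_factory=list)
    trigger_value: float = float("nan")
    refractory_left: int = 0

    @property
    def capture_count(self) -> int:
        return len(self.capture)


def push_sample(
    state: DetectorState, sample: float, config: DetectorConfig
) -> Tuple[DetectorState, Optional[EventWindow]]:
    """Feed one magnitude sample through the node algorithm.

    Total function of (state, sample): mutates and returns ``state`` together
    with an :class:`EventWindow` when a capture completes, else ``None``.
    Threshold crossings during an ongoing capture never re-trigger.
    """
    sample = float(sample)
    if state.mode == "monitoring":
        triggered = sample > config.threshold and state.refractory_left == 0
        if state.refractory_left > 0:
            state.refractory_left -= 1
        if triggered:
            state.mode = "capturing"
            state.trigger_value = sample
            state.capture = [sample]
        else:
            state.ring.append(sample)
            if len(state.ring) > config.pre_samples:
                del state.ring[0]
        if state.mode == "capturing" and state.capture_count >= config.post_samples:
            return state, _emit(state, config)  # degenerate post_samples == 1
        return state, None

    # capturing
    state.capture.append(sample)
    if state.capture_count >= config.post_samples:
        return state, _emit(state, config)
    return state, None


def _emit(state: DetectorState, config: DetectorConfig) -> EventWindow:
    pre = list(state.ring)
    pad_value = pre[0] if pre else state.capture[0]
    pre = [pad_value] * (config.pre_samples - len(pre)) + pre
    values = np.array(pre + state.capture, dtype=float)
    window = EventWindow(
        values=values,
        trigger_index=config.pre_samples,
        origin="streamed",
        trigger_value=state.trigger_value,
    )
    # "the buffer resets, resuming normal monitoring"
    state.ring = []
    state.capture = []
    state.mode = "monitoring"
    state.trigger_value = float("nan")
    state.refractory_left = config.refractory_samples
    return window


class StreamingDetector:
    """Stateful convenience wrapper around :func:`push_sample`."""

    def __init__(self, config: Optional[DetectorConfig] = None):
        self.config = config or DetectorConfig()
        self.state = DetectorState()

    def push(self, sample: float) -> Optional[EventWindow]:
        self.state, window = push_sample(self.state, sample, self.config)
        return window

    def process(self, samples) -> List[EventWindow]:
        out = []
        for s in np.asarray(samples, dtype=float):
            w = self.push(s)
            if w is not None:
                out.append(w)
        return out


def detect_events_offline(
    series: MagnitudeSeries, config: Optional[DetectorConfig] = None
) -> List[EventWindow]:
    """Brute-force scan equivalent of the streaming detector.

    Scans left to right for strict threshold crossings; a crossing inside a
    previous capture is suppressed, the pre-trigger history never reaches
    across an earlier window's reset point, and missing history at a cold
    start is filled by repeating the earliest available sample. A trigger too
    close to the end of the series to complete its 2-s post-capture emits
    nothing, exactly as the streaming node would still be capturing when the
    stream ends.
    """
    config = config or DetectorConfig()
    values = np.asarray(series.values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("series must be non-empty")
    if not math.isclose(series.fs, config.fs, rel_tol=1e-9):
        raise InvalidInputError(
            f"series rate {series.fs} Hz does not match detector rate {config.fs} Hz"
        )
    pre_n, post_n = config.pre_samples, config.post_samples
    windows: List[EventWindow] = []
    reset_idx = 0  # earliest index usable as pre-trigger history
    i = 0
    n = values.size
    while i < n:
        if values[i] > config.threshold:
            if i + post_n > n:
                break  # capture cannot complete before the stream ends
            pre = values[max(reset_idx, i - pre_n) : i]
            pad = pre[0] if pre.size else values[i]
            pre_full = np.concatenate([np.full(pre_n - pre.size, pad), pre])
            window_values = np.concatenate([pre_full, values[i : i + post_n]])
            windows.append(
                EventWindow(
                    values=window_values,
                    trigger_index=pre_n,
                    origin="streamed",
                    trigger_value=float(values[i]),
                )
            )
            reset_idx = i + post_n
            i = i + post_n + config.refractory_samples
        else:
            i += 1
    return windows


@dataclass(frozen=True)
class Packet:
    """A contiguous slice of an event window as sent over the radio link."""

    seq: int
    offset: int
    payload: np.ndarray
    attempts: int

    def __post_init__(self):
        object.__setattr__(self, "payload", np.asarray(self.payload, dtype=float))


def simulate_link(
    window: EventWindow,
    samples_per_packet: int = 20,
    loss_prob: float = 0.0,
    max_retransmissions: int = 3,
    seed: int = 0,
) -> List[Packet]:
    """Split a window into packets and deliver each over a Bernoulli-loss link.

    Each packet is attempted at most ``1 + max_retransmissions`` times; every
    attempt independently succeeds with probability ``1 − loss_prob``. Packets
    whose every attempt is lost are absent from the returned list. The call is
    deterministic given ``seed``.
    """
    if not 0 <= loss_prob < 1:
        raise InvalidInputError("loss_prob must lie in [0, 1)")
    if samples_per_packet < 1:
        raise InvalidInputError("samples_per_packet must be >= 1")
    if max_retransmissions < 0:
        raise InvalidInputError("max_retransmissions must be >= 0")
    rng = np.random.default_rng(seed)
    values = window.values
    delivered: List[Packet] = []
    n_packets = math.ceil(values.size / samples_per_packet)
    for seq in range(n_packets):
        offset = seq * samples_per_packet
        payload = values[offset : offset + samples_per_packet]
        attempts = 0
        ok = False
        while attempts < 1 + max_retransmissions and not ok:
            attempts += 1
            ok = rng.random() >= loss_prob
        if ok:
            delivered.append(Packet(seq=seq, offset=offset, payload=payload, attempts=attempts))
    return delivered


def gateway_reassemble(packets: List[Packet], expected_length: int = 80) -> EventWindow:
    """Rebuild a complete window from delivered packets by LOCF gap filling.

    Payloads are placed at their offsets; every missing sample is replaced by
    the most recent preceding valid sample, and a missing prefix by the first
    valid sample. With zero loss this is the identity.
    """
    if not packets:
        raise ReassemblyError("no packets delivered; event lost")
    values = np.full(expected_length, np.nan)
    for pkt in sorted(packets, key=lambda p: p.seq):
        end = pkt.offset + pkt.payload.size
        if end > expected_length:
            raise InvalidInputError("packet payload extends past the window")
        values[pkt.offset : end] = pkt.payload
    valid = np.flatnonzero(~np.isnan(values))
    # prefix fill, then carry forward
    values[: valid[0]] = values[valid[0]]
    for i in range(1, expected_length):
        if np.isnan(values[i]):
            values[i] = values[i - 1]
    trigger_index = min(expected_length - 1, expected_length // 2)
    return EventWindow(values=values, trigger_index=trigger_index, origin="reassembled")
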