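"""Seeded generator of synthetic fall and ADL accelerometer traces.

The generator reproduces the qualitative dynamics a waist-worn accelerometer
records: a fall is standing (~1 g) → a brief free-fall dip (magnitude well
below 1 g) → an impact spike exceeding 3 g → damped ringing → rest at ~1 g
with a changed orientation. ADLs are walking oscillation, sit/stand and
lie-down transients and bend-and-rise, all kept strictly below the 3 g
trigger threshold except for deliberate "distractor" spikes that cross 3 g
without the free-fall/orientation-change signature — the contrast the
confirmation classifier has to learn.

Every trace is reproducible from (master seed, subject index, trace index);
datasets can be written out as SisFall-style integer-count CSV files plus a
JSON manifest and read back with :mod:`fallkit.sisfall`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConfigurationError
from .signals import AccelTrace, DEFAULT_RANGE_G, DEFAULT_RESOLUTION_BITS

FALL_TYPES = ("forward", "lateral", "backward_rotation", "backward_supine")
ADL_TYPES = ("walk", "sit_stand", "lie_down", "bend")

# resting orientation (unit vector) after each fall type; standing is +Z up
_FALL_END_ORIENTATION = {
    "forward": (0.0, 0.96, 0.28),
    "lateral": (0.96, 0.0, 0.28),
    "backward_rotation": (0.0, -0.96, -0.28),
    "backward_supine": (0.0, -0.28, -0.96),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic corpus (all accelerations in g)."""

    fs: float = 200.0
    fall_duration_s: float = 10.0
    adl_duration_s: float = 14.0
    fall_impact_peak_g: Tuple[float, float] = (3.5, 8.0)
    freefall_dip_g: Tuple[float, float] = (0.2, 0.6)
    freefall_duration_s: Tuple[float, float] = (0.3, 0.5)
    impact_plateau_s: float = 0.1
    distractor_peak_g: Tuple[float, float] = (3.4, 3.8)
    distractor_prob: float = 0.05
    adl_peak_cap_g: float = 2.4
    noise_sd_g: float = 0.03
    n_subjects: int = 10
    falls_per_subject: int = 15
    adls_per_subject: int = 19
    per_subject_scale_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (
            self.fall_impact_peak_g,
            self.freefall_dip_g,
            self.freefall_duration_s,
            self.distractor_peak_g,
        ):
            if not (0 < lo <= hi):
                raise ConfigurationError("ranges must be positive and ordered")
        if self.fall_impact_peak_g[0] <= 3.0 or self.distractor_peak_g[0] <= 3.0:
            raise ConfigurationError("impact and distractor peaks must exceed 3 g")
        if not 0 <= self.distractor_prob <= 1:
            raise ConfigurationError("distractor_prob must lie in [0, 1]")
        if (self.fs * self.fall_duration_s) % 1 or (self.fs * self.adl_duration_s) % 1:
            raise ConfigurationError("fs * duration must be an integer sample count")


def _smoothstep(n: int) -> np.ndarray:
    """Cosine ramp from 0 to 1 over n samples."""
    if n <= 0:
        return np.zeros(0)
    x = np.linspace(0.0, 1.0, n)
    return 0.5 - 0.5 * np.cos(np.pi * x)


def _slerp(u0: np.ndarray, u1: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors, one row per frac value."""
    dot = float(np.clip(np.dot(u0, u1), -1.0, 1.0))
    theta = math.acos(dot)
    if theta < 1e-9:
        return np.tile(u0, (frac.size, 1))
    s = math.sin(theta)
    a = np.sin((1 - frac) * theta) / s
    b = np.sin(frac * theta) / s
    return a[:, None] * u0[None, :] + b[:, None] * u1[None, :]


def _assemble(mag: np.ndarray, orient: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    """Distribute a magnitude envelope along orientations and add axis noise."""
    sig = mag[:, None] * orient
    sig += rng.normal(0.0, noise_sd, size=sig.shape)
    return sig


def generate_fall_trace(
    config: SyntheticConfig,
    subject_id: str,
    fall_type: str,
    seed: int,
    activity_code: str = "",
    subject_scale: float = 1.0,
) -> AccelTrace:
    """One synthetic fall: stand → free-fall dip → >3 g impact → ringing → rest."""
    if fall_type not in FALL_TYPES:
        raise ConfigurationError(f"unknown fall type {fall_type!r}")
    rng = np.random.default_rng(seed)
    fs = config.fs
    n = int(round(fs * config.fall_duration_s))
    mag = np.ones(n)

    dip = rng.uniform(*config.freefall_dip_g)
    dip_dur = rng.uniform(*config.freefall_duration_s)
    peak = rng.uniform(*config.fall_impact_peak_g) * subject_scale
    peak = max(peak, config.fall_impact_peak_g[0])  # jitter never erodes the 3 g margin
    # event placed so that 2 s of pre- and post-impact context always exist
    t_ff = rng.uniform(3.0, config.fall_duration_s - 4.0)
    i_ff = int(t_ff * fs)
    n_ff = int(dip_dur * fs)
    n_rise = int(0.05 * fs)
    n_plateau = int(config.impact_plateau_s * fs)
    n_ring = int(0.8 * fs)

    # free-fall: magnitude decays towards the dip value
    mag[i_ff : i_ff + n_ff] = 1.0 + (dip - 1.0) * _smoothstep(n_ff)
    i = i_ff + n_ff
    # impact rise and plateau (plateau guarantees >3 g survives 200→20 Hz decimation)
    mag[i : i + n_rise] = dip + (peak - dip) * _smoothstep(n_rise)
    i += n_rise
    mag[i : i + n_plateau] = peak
    i += n_plateau
    # damped post-impact ringing settling at 1 g
    tt = np.arange(min(n_ring, n - i)) / fs
    ring = 1.0 + (peak - 1.0) * np.exp(-tt / 0.12) * np.cos(2 * np.pi * 3.0 * tt) * 0.35
    mag[i : i + tt.size] = np.clip(ring, 0.05, peak)
    # remainder stays at rest (1 g)

    u0 = np.array([0.0, 0.0, 1.0])
    u1 = np.array(_FALL_END_ORIENTATION[fall_type])
    u1 = u1 / np.linalg.norm(u1)
    orient = np.tile(u0, (n, 1))
    n_rot = i + tt.size - i_ff
    orient[i_ff : i_ff + n_rot] = _slerp(u0, u1, _smoothstep(n_rot))
    orient[i_ff + n_rot :] = u1

    sig = _assemble(mag, orient, config.noise_sd_g, rng)
    return AccelTrace(
        ax=sig[:, 0],
        ay=sig[:, 1],
        az=sig[:, 2],
        fs=fs,
        subject_id=subject_id,
        activity_code=activity_code or f"F_{fall_type}",
        is_fall=True,
        meta={"fall_type": fall_type, "peak_g": float(peak), "impact_t": i_ff / fs},
    )


def _adl_envelope(adl_type: str, n: int, fs: float, rng, scale: float) -> Tuple[np.ndarray, np.ndarray]:
    """Magnitude envelope and orientation path for one ADL, all sub-threshold."""
    t = np.arange(n) / fs
    u0 = np.array([0.0, 0.0, 1.0])
    orient = np.tile(u0, (n, 1))
    mag = np.ones(n)
    if adl_type == "walk":
        amp = rng.uniform(0.2, 0.5) * scale
        freq = rng.uniform(1.7, 2.3)
        mag = 1.0 + amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        # gentle lateral sway so the axes are not degenerate
        sway = 0.08 * np.sin(2 * np.pi * freq / 2 * t)
        orient[:, 0] += sway
        orient /= np.linalg.norm(orient, axis=1, keepdims=True)
    else:
        # three well-separated transients so every trace offers >= 3 windows
        centers = np.sort(rng.uniform(1.5, n / fs - 1.5, size=3))
        heights = {
            "sit_stand": (1.8, 0.7),
            "lie_down": (1.5, 0.8),
            "bend": (2.0, 0.6),
        }[adl_type]
        for j, c in enumerate(centers):
            width = rng.uniform(0.4, 0.8)
            bump = (heights[0] - 1.0) * scale * np.exp(-0.5 * ((t - c) / (width / 2)) ** 2)
            dipw = rng.uniform(0.5, 1.0)
            dip = (1.0 - heights[1]) * np.exp(-0.5 * ((t - c - width) / (dipw / 2)) ** 2)
            mag += bump - dip
        if adl_type == "lie_down":
            u1 = np.array([0.0, 0.96, 0.28])
            k = int(centers[0] * fs)
            span = min(n - k, int(2.0 * fs))
            orient[k : k + span] = _slerp(u0, u1 / np.linalg.norm(u1), _smoothstep(span))
            orient[k + span :] = u1 / np.linalg.norm(u1)
    return mag, orient


def generate_adl_trace(
    config: SyntheticConfig,
    subject_id: str,
    adl_type: str,
    seed: int,
    activity_code: str = "",
    subject_scale: float = 1.0,
    force_distractor: Optional[bool] = None,
) -> AccelTrace:
    """One synthetic ADL; may carry a >3 g distractor spike without fall signature."""
    if adl_type not in ADL_TYPES:
        raise ConfigurationError(f"unknown ADL type {adl_type!r}")
    rng = np.random.default_rng(seed)
    fs = config.fs
    n = int(round(fs * config.adl_duration_s))
    mag, orient = _adl_envelope(adl_type, n, fs, rng, subject_scale)
    # hard sub-threshold guarantee for the envelope; noise is ~0.03 g per axis
    mag = np.clip(mag, 0.3, config.adl_peak_cap_g)

    distractor = rng.random() < config.distractor_prob
    if force_distractor is not None:
        distractor = bool(force_distractor)
    if distractor:
        peak = rng.uniform(*config.distractor_peak_g)
        c = int(rng.uniform(2.5, config.adl_duration_s - 2.5) * fs)
        n_rise = int(0.05 * fs)
        n_plateau = int(config.impact_plateau_s * fs)
        seg = slice(c, c + n_rise)
        base = mag[c]
        mag[seg] = base + (peak - base) * _smoothstep(n_rise)
        mag[c + n_rise : c + n_rise + n_plateau] = peak
        fall_ramp = slice(c + n_rise + n_plateau, c + 2 * n_rise + n_plateau)
        m = mag[fall_ramp].size
        mag[fall_ramp] = peak + (base - peak) * _smoothstep(m)

    sig = _assemble(mag, orient, config.noise_sd_g, rng)
    return AccelTrace(
        ax=sig[:, 0],
        ay=sig[:, 1],
        az=sig[:, 2],
        fs=fs,
        subject_id=subject_id,
        activity_code=activity_code or f"D_{adl_type}",
        is_fall=False,
        meta={"adl_type": adl_type, "distractor": bool(distractor)},
    )


def _trace_seed(master_seed: int, subject_index: int, trace_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), subject_index, trace_index])
    return int(ss.generate_state(1)[0])


def generate_dataset(
    config: Optional[SyntheticConfig] = None,
    out_dir: Optional[Path] = None,
) -> Tuple[List[AccelTrace], List[dict]]:
    """Generate the full synthetic corpus: per subject, falls plus ADLs.

    The corpus mirrors the shape of the public fall repository the pipeline
    was designed around: 10 subjects, 15 fall traces and 19 ADL traces each,
    with per-subject amplitude jitter. Returns traces plus a manifest; when
    ``out_dir`` is given, traces are additionally written as SisFall-style
    integer-count CSV files with a ``manifest.json``.
    """
    config = config or SyntheticConfig()
    if config.n_subjects < 4:
        raise ConfigurationError("need at least 4 subjects for subject-wise splits")
    traces: List[AccelTrace] = []
    manifest: List[dict] = []
    for si in range(config.n_subjects):
        subject_id = f"SY{si + 1:02d}"
        subj_rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), si])
        )
        scale = 1.0 + subj_rng.uniform(
            -config.per_subject_scale_jitter, config.per_subject_scale_jitter
        )
        for fi in range(config.falls_per_subject):
            code = f"F{fi + 1:02d}"
            fall_type = FALL_TYPES[fi % len(FALL_TYPES)]
            seed = _trace_seed(config.seed, si, fi)
            trace = generate_fall_trace(
                config, subject_id, fall_type, seed, activity_code=code, subject_scale=scale
            )
            traces.append(trace)
        for ai in range(config.adls_per_subject):
            code = f"D{ai + 1:02d}"
            adl_type = ADL_TYPES[ai % len(ADL_TYPES)]
            seed = _trace_seed(config.seed, si, config.falls_per_subject + ai)
            trace = generate_adl_trace(
                config, subject_id, adl_type, seed, activity_code=code, subject_scale=scale
            )
            traces.append(trace)
    for trace in traces:
        entry = {
            "file": f"{trace.activity_code}_{trace.subject_id}_R01.txt",
            "subject_id": trace.subject_id,
            "activity_code": trace.activity_code,
            "is_fall": trace.is_fall,
            "fs": trace.fs,
        }
        entry.update(trace.meta)
        manifest.append(entry)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for trace, entry in zip(traces, manifest):
            write_sisfall_csv(trace, out_dir / entry["file"])
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return traces, manifest


def write_sisfall_csv(trace: AccelTrace, path: Path) -> None:
    """Write a trace as SisFall-style rows of integer counts ``x,y,z;``.

    Counts quantize g values at 1/256 g per count (±16 g, 13-bit); the round
    trip back through :func:`fallkit.sisfall.read_trace` therefore perturbs
    each axis by at most half a count.
    """
    scale = float(2**DEFAULT_RESOLUTION_BITS) / (2.0 * DEFAULT_RANGE_G)
    counts = np.column_stack(
        [
            np.round(trace.ax * scale).astype(int),
            np.round(trace.ay * scale).astype(int),
            np.round(trace.az * scale).astype(int),
        ]
    )
    with open(path, "w") as fh:
        for row in counts:
            fh.write(f"{row[0]},{row[1]},{row[2]};\n")
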