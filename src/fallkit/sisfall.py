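"""SisFall-format trace reading and training-pattern construction.

A SisFall-style trace file is plain text, one row per 200 Hz sample, with
comma-separated integer sensor counts (rows may end in ``;``). Only the first
three columns — the ADXL345 X/Y/Z counts — are used; any further columns
(second accelerometer, gyroscope) are ignored. Counts are converted to g at
1/256 g per count (±16 g, 13-bit).

Pattern construction follows the deployed protocol: each fall trace yields one
4-s window centered on the global magnitude maximum; each ADL trace yields up
to three non-overlapping 4-s windows around its highest local maxima (the
segments most likely to be confused with a fall). Windows are decimated from
200 Hz to 20 Hz, the magnitude is computed after decimation, and subjects are
partitioned 6/2/2 into train/validation/test so no subject leaks across
splits (leave-2-subjects-out).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigurationError, TraceParseError, TraceTooShortError
from .signals import AccelTrace, decimate_array, magnitude, raw_counts_to_g

WINDOW_SECONDS = 4.0
TARGET_FS = 20.0
WINDOW_SAMPLES = int(WINDOW_SECONDS * TARGET_FS)  # 80

_FILENAME_RE = re.compile(r"^(?P<act>[A-Za-z]\d+)_(?P<subj>[A-Za-z]+\d+)_R(?P<trial>\d+)$")


@dataclass(frozen=True)
class Pattern:
    """An 80-sample magnitude window at 20 Hz with its class label."""

    values: np.ndarray
    label: int  # 1 = fall, 0 = ADL
    subject_id: str = ""
    activity_code: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (WINDOW_SAMPLES,):
            raise ConfigurationError(
                f"pattern must have exactly {WINDOW_SAMPLES} samples, got {self.values.shape}"
            )
        if self.label not in (0, 1):
            raise ConfigurationError("label must be 0 (ADL) or 1 (fall)")


@dataclass(frozen=True)
class SplitSpec:
    """Subject-wise split; subjects never appear in more than one set."""

    train_subjects: Tuple[str, ...]
    val_subjects: Tuple[str, ...]
    test_subjects: Tuple[str, ...]

    def __post_init__(self):
        groups = (set(self.train_subjects), set(self.val_subjects), set(self.test_subjects))
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ConfigurationError("split subject sets must be disjoint")

    @property
    def all_subjects(self) -> set:
        return set(self.train_subjects) | set(self.val_subjects) | set(self.test_subjects)


def parse_filename(path: Union[str, Path]) -> Tuple[str, str, int, bool]:
    """Parse ``<ACT>_<SUBJ>_R<trial>`` metadata from a trace filename."""
    stem = Path(path).stem
    m = _FILENAME_RE.match(stem)
    if not m:
        raise ConfigurationError(
            f"filename {stem!r} does not match the <ACT>_<SUBJ>_R<trial> convention"
        )
    act = m.group("act")
    return act, m.group("subj"), int(m.group("trial")), act.upper().startswith("F")


def read_trace(
    path: Union[str, Path],
    fs_native: float = 200.0,
    subject_id: Optional[str] = None,
    activity_code: Optional[str] = None,
    is_fall: Optional[bool] = None,
) -> AccelTrace:
    """Read a SisFall-style file into an :class:`AccelTrace` in g.

    Metadata defaults are parsed from the filename; pass them explicitly (or
    via a manifest) to override. Malformed rows raise a parse error naming the
    offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if subject_id is None or activity_code is None or is_fall is None:
        act, subj, _trial, fall = parse_filename(path)
        subject_id = subject_id if subject_id is not None else subj
        activity_code = activity_code if activity_code is not None else act
        is_fall = is_fall if is_fall is not None else fall
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().rstrip(";").strip()
            if not line:
                continue
            cells = [c.strip() for c in line.split(",") if c.strip() != ""]
            if len(cells) < 3:
                raise TraceParseError(path, lineno, f"expected >= 3 columns, got {len(cells)}")
            try:
                rows.append((int(cells[0]), int(cells[1]), int(cells[2])))
            except ValueError as exc:
                raise TraceParseError(path, lineno, f"non-integer cell: {exc}") from None
    if not rows:
        raise TraceParseError(path, 0, "file contains no samples")
    counts = np.array(rows, dtype=int)
    g = raw_counts_to_g(counts)
    return AccelTrace(
        ax=g[:, 0],
        ay=g[:, 1],
        az=g[:, 2],
        fs=fs_native,
        subject_id=subject_id,
        activity_code=activity_code,
        is_fall=is_fall,
    )


def read_dataset(
    input_dir: Union[str, Path],
    manifest: Optional[List[dict]] = None,
    fs_native: float = 200.0,
) -> List[AccelTrace]:
    """Read every trace file in a directory (optionally driven by a manifest)."""
    input_dir = Path(input_dir)
    traces = []
    if manifest is not None:
        for entry in manifest:
            traces.append(
                read_trace(
                    input_dir / entry["file"],
                    fs_native=entry.get("fs", fs_native),
                    subject_id=entry.get("subject_id"),
                    activity_code=entry.get("activity_code"),
                    is_fall=entry.get("is_fall"),
                )
            )
        return traces
    for path in sorted(input_dir.glob("*.txt")):
        traces.append(read_trace(path, fs_native=fs_native))
    return traces


def _decimation_factor(fs: float) -> int:
    factor = fs / TARGET_FS
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ConfigurationError(f"native rate {fs} Hz is not an integer multiple of 20 Hz")
    return int(round(factor))


def _window_at(trace: AccelTrace, center: int) -> np.ndarray:
    """80-sample magnitude window (20 Hz) centered on a native-rate index."""
    n = len(trace)
    half = int(WINDOW_SECONDS * trace.fs / 2)
    native = 2 * half
    if n < native:
        raise TraceTooShortError(
            f"trace of {n} samples is shorter than one {native}-sample window"
        )
    start = min(max(center - half, 0), n - native)
    factor = _decimation_factor(trace.fs)
    sl = slice(start, start + native)
    ax = decimate_array(trace.ax[sl], factor)
    ay = decimate_array(trace.ay[sl], factor)
    az = decimate_array(trace.az[sl], factor)
    return magnitude(ax, ay, az)


def extract_fall_window(trace: AccelTrace) -> Pattern:
    """The single 4-s window centered on the trace's global magnitude maximum.

    Ties break to the earliest index; near the trace boundaries the window is
    clamped so it stays inside the trace while keeping its full length.
    """
    mag = trace.magnitude_series().values
    peak = int(np.argmax(mag))  # argmax returns the earliest maximum
    values = _window_at(trace, peak)
    return Pattern(
        values=values,
        label=1,
        subject_id=trace.subject_id,
        activity_code=trace.activity_code,
        meta={"center_index": peak, **trace.meta},
    )


def extract_adl_windows(
    trace: AccelTrace, k: int = 3, min_separation_s: float = WINDOW_SECONDS
) -> List[Pattern]:
    """Up to ``k`` non-overlapping 4-s windows around the highest local maxima.

    Local maxima of the native-rate magnitude are ranked by height and
    selected greedily, rejecting any candidate whose center is closer than
    ``min_separation_s`` to an already selected one. Short traces yield fewer
    than ``k`` windows (at least one, centered on the global maximum).
    """
    mag = trace.magnitude_series().values
    peaks, props = find_peaks(mag, height=-np.inf)
    candidates = list(peaks)
    heights = list(props["peak_heights"])
    gmax = int(np.argmax(mag))
    if gmax not in candidates:
        candidates.append(gmax)
        heights.append(float(mag[gmax]))
    order = sorted(range(len(candidates)), key=lambda i: (-heights[i], candidates[i]))
    min_sep = int(min_separation_s * trace.fs)
    n = len(trace)
    half = int(WINDOW_SECONDS * trace.fs / 2)

    def clamped_start(center: int) -> int:
        return min(max(center - half, 0), n - 2 * half)

    # non-overlap is judged on the boundary-clamped windows, so traces barely
    # longer than one window still yield exactly one pattern
    chosen: List[int] = []
    for idx in order:
        c = candidates[idx]
        if all(abs(clamped_start(c) - clamped_start(o)) >= min_sep for o in chosen):
            chosen.append(c)
        if len(chosen) == k:
            break
    patterns = []
    for c in sorted(chosen):
        patterns.append(
            Pattern(
                values=_window_at(trace, c),
                label=0,
                subject_id=trace.subject_id,
                activity_code=trace.activity_code,
                meta={"center_index": int(c), **trace.meta},
            )
        )
    return patterns


def patterns_from_traces(traces: Iterable[AccelTrace], k_adl: int = 3) -> List[Pattern]:
    """Apply the fall/ADL windowing protocol to a whole corpus."""
    patterns: List[Pattern] = []
    for trace in traces:
        if trace.is_fall:
            patterns.append(extract_fall_window(trace))
        else:
            patterns.extend(extract_adl_windows(trace, k=k_adl))
    return patterns


def make_split(subject_ids: Sequence[str], seed: int) -> SplitSpec:
    """Shuffle subjects deterministically and cut 60/20/20 by subject."""
    subjects = sorted(set(subject_ids))
    n = len(subjects)
    n_train = int(round(0.6 * n))
    n_val = int(round(0.2 * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ConfigurationError(f"cannot cut {n} subjects into 60/20/20 non-empty sets")
    rng = np.random.default_rng(seed)
    perm = [subjects[i] for i in rng.permutation(n)]
    return SplitSpec(
        train_subjects=tuple(perm[:n_train]),
        val_subjects=tuple(perm[n_train : n_train + n_val]),
        test_subjects=tuple(perm[n_train + n_val :]),
    )


def partition_by_subject(
    patterns: Sequence[Pattern],
    split: Union[SplitSpec, int],
    expected_subjects: Optional[int] = 10,
) -> Tuple[List[Pattern], List[Pattern], List[Pattern]]:
    """Assign every pattern to its subject's split; no subject leaks.

    ``split`` is an explicit :class:`SplitSpec` or a seed from which subjects
    are shuffled and cut 6/2/2 (60/20/20 for other subject counts).
    """
    present = sorted({p.subject_id for p in patterns})
    if expected_subjects is not None and len(present) != expected_subjects:
        raise ConfigurationError(
            f"expected {expected_subjects} distinct subjects, found {len(present)}"
        )
    if isinstance(split, SplitSpec):
        if split.all_subjects != set(present):
            raise ConfigurationError("split subjects do not match the subjects present")
    else:
        split = make_split(present, int(split))
    groups = {s: 0 for s in split.train_subjects}
    groups.update({s: 1 for s in split.val_subjects})
    groups.update({s: 2 for s in split.test_subjects})
    out: Tuple[List[Pattern], List[Pattern], List[Pattern]] = ([], [], [])
    for p in patterns:
        out[groups[p.subject_id]].append(p)
    return out


def patterns_to_dataframe(patterns: Sequence[Pattern]) -> pd.DataFrame:
    """80 value columns plus label/subject/activity, one row per pattern."""
    data = {f"v{i:02d}": [p.values[i] for p in patterns] for i in range(WINDOW_SAMPLES)}
    data["label"] = [p.label for p in patterns]
    data["subject_id"] = [p.subject_id for p in patterns]
    data["activity_code"] = [p.activity_code for p in patterns]
    return pd.DataFrame(data)


def dataframe_to_patterns(df: pd.DataFrame) -> List[Pattern]:
    cols = [f"v{i:02d}" for i in range(WINDOW_SAMPLES)]
    return [
        Pattern(
            values=row[cols].to_numpy(dtype=float),
            label=int(row["label"]),
            subject_id=str(row["subject_id"]),
            activity_code=str(row["activity_code"]),
        )
        for _, row in df.iterrows()
    ]
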