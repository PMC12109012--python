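"""Shared signal math: unit conversion, magnitude, decimation, Z-score.

All acceleration values inside fallkit are expressed in g (1 g = 9.81 m/s²);
conversion to m/s² happens only at reporting boundaries. The waist-worn sensor
is an ADXL345-class accelerometer delivering signed integer counts at a native
200 Hz, with a ±16 g full-scale range and 13-bit resolution, so one count is
2·16/2¹³ = 1/256 g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateStatisticsError, InvalidInputError

STANDARD_GRAVITY_MS2 = 9.81
#: counts → g scale for a ±16 g, 13-bit accelerometer: 2·range / 2^bits
DEFAULT_RANGE_G = 16.0
DEFAULT_RESOLUTION_BITS = 13


@dataclass(frozen=True)
class NormStats:
    """Pooled mean/standard deviation of the training magnitudes, in g."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not np.isfinite(self.mu) or not np.isfinite(self.sigma):
            raise InvalidInputError("normalization statistics must be finite")
        if self.sigma <= 0:
            raise DegenerateStatisticsError("sigma must be positive")


@dataclass(frozen=True)
class MagnitudeSeries:
    """Ordered acceleration-magnitude samples (g) at a fixed rate."""

    values: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")
        if self.values.ndim != 1:
            raise InvalidInputError("magnitude series must be one-dimensional")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class AccelTrace:
    """Triaxial acceleration series in g with sampling rate and labels.

    ``ax``, ``ay``, ``az`` are equal-length float arrays; ``t`` is derived as
    ``arange(n)/fs`` (seconds from trace start). ``activity_code`` follows the
    SisFall naming scheme (D01…D19 for ADLs, F01…F15 for falls) or a synthetic
    tag; ``is_fall`` is the ground truth used for evaluation.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    subject_id: str = ""
    activity_code: str = ""
    is_fall: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (self.ax.shape == self.ay.shape == self.az.shape):
            raise InvalidInputError("axis arrays must have identical shape")
        if self.ax.ndim != 1:
            raise InvalidInputError("axis arrays must be one-dimensional")
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")
        if not (
            np.all(np.isfinite(self.ax))
            and np.all(np.isfinite(self.ay))
            and np.all(np.isfinite(self.az))
        ):
            raise InvalidInputError("acceleration components must be finite")

    def __len__(self) -> int:
        return self.ax.size

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def magnitude_series(self) -> MagnitudeSeries:
        return MagnitudeSeries(magnitude(self.ax, self.ay, self.az), self.fs)


def magnitude(ax, ay, az):
    """Euclidean norm of the triaxial acceleration, in g.

    Accepts scalars or equal-shaped arrays; the result is orientation
    invariant, which is why the sensor node transmits the magnitude instead of
    the three components.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(ay)) and np.all(np.isfinite(az))):
        raise InvalidInputError("acceleration components must be finite")
    out = np.sqrt(ax * ax + ay * ay + az * az)
    return float(out) if out.ndim == 0 else out


def raw_counts_to_g(
    counts,
    range_g: float = DEFAULT_RANGE_G,
    resolution_bits: int = DEFAULT_RESOLUTION_BITS,
):
    """Convert signed integer sensor counts to g: (2·range / 2^bits)·counts."""
    if resolution_bits < 1:
        raise InvalidInputError("resolution_bits must be >= 1")
    if range_g <= 0:
        raise InvalidInputError("range_g must be positive")
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer):
        # accept floats that are exactly integral (e.g. pandas parse output)
        flo = np.asarray(arr, dtype=float)
        if not np.all(np.isfinite(flo)) or not np.all(flo == np.round(flo)):
            raise InvalidInputError("counts must be integers")
        arr = flo
    scale = 2.0 * range_g / float(2**resolution_bits)
    out = scale * np.asarray(arr, dtype=float)
    return float(out) if out.ndim == 0 else out


def g_to_ms2(value):
    """Convert g to m/s² with standard gravity 9.81 (3 g → 29.43 m/s²)."""
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("value must be finite")
    out = arr * STANDARD_GRAVITY_MS2
    return float(out) if out.ndim == 0 else out


def decimate_array(values: np.ndarray, factor: int) -> np.ndarray:
    """Plain decimation: keep every ``factor``-th sample starting at index 0."""
    if int(factor) != factor or factor < 1:
        raise InvalidInputError("decimation factor must be a positive integer")
    return np.asarray(values)[:: int(factor)]


def downsample(series, factor: int):
    """Downsample a MagnitudeSeries or AccelTrace by plain decimation.

    No anti-alias filter is applied: decimation of an 800-sample 200 Hz
    segment yields exactly the 80 samples at 20 Hz that the deployed firmware
    would have captured natively.
    """
    if int(factor) != factor or factor < 1:
        raise InvalidInputError("decimation factor must be a positive integer")
    factor = int(factor)
    if isinstance(series, MagnitudeSeries):
        if len(series) == 0:
            raise InvalidInputError("series must be non-empty")
        return MagnitudeSeries(decimate_array(series.values, factor), series.fs / factor)
    if isinstance(series, AccelTrace):
        if len(series) == 0:
            raise InvalidInputError("series must be non-empty")
        return AccelTrace(
            ax=decimate_array(series.ax, factor),
            ay=decimate_array(series.ay, factor),
            az=decimate_array(series.az, factor),
            fs=series.fs / factor,
            subject_id=series.subject_id,
            activity_code=series.activity_code,
            is_fall=series.is_fall,
            meta=dict(series.meta),
        )
    raise InvalidInputError(f"cannot downsample object of type {type(series).__name__}")


def zscore_fit(training_windows: Iterable[Sequence[float]]) -> NormStats:
    """Pooled mean/sd over every sample of every training window.

    Uses the population standard deviation (divide by N) over the flattened
    pool; the statistics are frozen with the model and reused verbatim at
    inference time.
    """
    pool = np.concatenate([np.asarray(w, dtype=float).ravel() for w in training_windows])
    if pool.size < 2:
        raise InvalidInputError("need at least two pooled samples")
    mu = float(np.mean(pool))
    sigma = float(np.std(pool))  # population sd
    if sigma == 0.0:
        raise DegenerateStatisticsError("training pool has zero variance")
    return NormStats(mu=mu, sigma=sigma)


def zscore_apply(window, stats: NormStats):
    """Map each magnitude X to (X − μ)/σ using frozen training statistics."""
    if stats.sigma <= 0:
        raise DegenerateStatisticsError("sigma must be positive")
    arr = np.asarray(window, dtype=float)
    return (arr - stats.mu) / stats.sigma
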