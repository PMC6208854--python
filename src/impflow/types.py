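"""Core containers shared across the package.

A dynamic planar study is a stack of short frames; every curve in the
pipeline is carried as a :class:`TAC` — values sampled at frame mid-times,
with an explicit unit tag so that calibrated and relative analyses cannot
be silently mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TimeGrid", "TAC", "VALID_UNITS", "DataError", "ConfigError"]

#: unit tags a TAC may carry
VALID_UNITS = frozenset(
    {"counts", "Bq", "Bq/mL", "Bq/g", "dimensionless",
     "counts*min", "Bq*min", "Bq*min/mL", "Bq*min/g"}
)

# unit produced by cumulative integration over time (minutes)
_INTEGRAL_UNIT = {
    "counts": "counts*min",
    "Bq": "Bq*min",
    "Bq/mL": "Bq*min/mL",
    "Bq/g": "Bq*min/g",
    "dimensionless": "dimensionless",
}


class DataError(ValueError):
    """Malformed or physically inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration."""


@dataclass(frozen=True)
class TimeGrid:
    """Frame timing of a dynamic acquisition.

    Parameters
    ----------
    frame_start : array-like, min
        Start time of each frame.
    frame_duration : array-like, min
        Duration of each frame.  Scalar broadcasts to all frames.

    The default clinical protocol is 60 frames of 2 s; use
    :meth:`TimeGrid.default`.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.broadcast_to(
            np.asarray(self.frame_duration, dtype=float), start.shape
        ).copy()
        if start.ndim != 1 or start.size == 0:
            raise ConfigError("frame_start must be a non-empty 1-D array")
        if np.any(np.diff(start) <= 0):
            raise ConfigError("frame starts must be strictly increasing")
        if np.any(dur <= 0):
            raise ConfigError("frame durations must be positive")
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)

    @classmethod
    def default(cls, n_frames: int = 60, frame_s: float = 2.0) -> "TimeGrid":
        """Contiguous grid of ``n_frames`` frames of ``frame_s`` seconds."""
        dur = frame_s / 60.0
        return cls(np.arange(n_frames) * dur, dur)

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-point times in minutes."""
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def end_time(self) -> float:
        """End of the last frame, minutes."""
        return float(self.frame_start[-1] + self.frame_duration[-1])

    def refined(self, factor: int) -> "TimeGrid":
        """Grid with each frame split into ``factor`` equal sub-frames."""
        if factor < 1:
            raise ConfigError("refinement factor must be >= 1")
        sub = np.arange(factor) / factor
        starts = (self.frame_start[:, None]
                  + self.frame_duration[:, None] * sub[None, :]).ravel()
        durs = np.repeat(self.frame_duration / factor, factor)
        return TimeGrid(starts, durs)


@dataclass(frozen=True)
class TAC:
    """A time–activity curve: values sampled at strictly increasing times.

    ``times`` are in minutes (frame mid-points for frame data); ``unit``
    must be one of :data:`VALID_UNITS`.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = "dimensionless"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size or t.size == 0:
            raise DataError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise DataError("TAC times must be strictly increasing")
        if self.unit not in VALID_UNITS:
            raise DataError(f"unknown unit tag {self.unit!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "TAC":
        return TAC(self.times, np.asarray(values, float),
                   self.unit if unit is None else unit)

    def integral_unit(self) -> str:
        try:
            return _INTEGRAL_UNIT[self.unit]
        except KeyError:
            raise DataError(
                f"cannot integrate a TAC already in integral unit {self.unit!r}"
            ) from None

    def same_grid(self, other: "TAC", rtol: float = 1e-9) -> bool:
        return (len(self) == len(other)
                and bool(np.allclose(self.times, other.times, rtol=rtol, atol=1e-12)))
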