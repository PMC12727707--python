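"""Core record types shared across the pipeline.

Epoch-level accelerometer data are held as plain numpy arrays inside small
dataclasses; timestamps are naive local clock time (``numpy.datetime64[s]``)
and daylight-saving transitions are explicitly out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["EpochSeries", "DayWindow", "SleepAnnotation"]


def _as_dt64(ts) -> np.datetime64:
    return np.datetime64(ts, "s")


@dataclass
class EpochSeries:
    """One participant's uniformly sampled epoch record.

    Parameters
    ----------
    participant_id : str
        Identifier, consistent across all cohort tables.
    start : numpy.datetime64
        Timestamp of the first epoch's left edge. Epochs are half-open
        ``[t, t + epoch_len_s)``.
    epoch_len_s : int
        Epoch length in seconds; must divide 3600.
    enmo : ndarray of float
        Euclidean Norm Minus One per epoch, in milli-g, non-negative.
    wear : ndarray of bool
        Per-epoch wear flag.
    lux_hi : ndarray of bool, optional
        Per-epoch flag for light exposure above 1000 lux.
    """

    participant_id: str
    start: np.datetime64
    epoch_len_s: int
    enmo: np.ndarray
    wear: np.ndarray
    lux_hi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.start = _as_dt64(self.start)
        self.enmo = np.asarray(self.enmo, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.enmo.ndim != 1:
            raise ValueError("enmo must be one-dimensional")
        if self.wear.shape != self.enmo.shape:
            raise ValueError("wear and enmo must have equal length")
        if self.lux_hi is not None:
            self.lux_hi = np.asarray(self.lux_hi, dtype=bool)
            if self.lux_hi.shape != self.enmo.shape:
                raise ValueError("lux_hi and enmo must have equal length")
        if self.epoch_len_s <= 0 or 3600 % int(self.epoch_len_s) != 0:
            raise ValueError("epoch_len_s must be a positive divisor of 3600")
        if self.enmo.size and np.nanmin(self.enmo) < 0:
            raise ValueError("ENMO values must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.enmo.size

    @property
    def epoch_hours(self) -> float:
        return self.epoch_len_s / 3600.0

    def times(self) -> np.ndarray:
        """Left-edge timestamps of every epoch."""
        return self.start + np.arange(self.n_epochs) * np.timedelta64(
            self.epoch_len_s, "s"
        )

    def clock_hours(self) -> np.ndarray:
        """Hours since midnight of each epoch's day, in [0, 24)."""
        return (self.hours_since_start() + self.start_clock_hour()) % 24.0

    def hours_since_start(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_hours

    def start_clock_hour(self) -> float:
        midnight = self.start.astype("datetime64[D]").astype("datetime64[s]")
        return float((self.start - midnight) / np.timedelta64(1, "h"))

    def index_of(self, ts) -> int:
        """Index of the epoch containing ``ts`` (may be out of range)."""
        delta = (_as_dt64(ts) - self.start) / np.timedelta64(self.epoch_len_s, "s")
        return int(np.floor(delta))

    def clip_index(self, ts) -> int:
        return min(max(self.index_of(ts), 0), self.n_epochs)

    def time_at(self, idx: int) -> np.datetime64:
        return self.start + np.timedelta64(int(idx) * self.epoch_len_s, "s")


@dataclass
class SleepAnnotation:
    """Sleep-period boundaries for one night (noon-to-noon anchored)."""

    night_index: int
    onset: np.datetime64
    wake: np.datetime64
    source: str = "algorithmic"  # {"algorithmic", "diary_guided", "diary"}

    def __post_init__(self) -> None:
        self.onset = _as_dt64(self.onset)
        self.wake = _as_dt64(self.wake)
        if not self.onset < self.wake:
            raise ValueError("sleep onset must precede waking")
        if (self.wake - self.onset) / np.timedelta64(1, "h") >= 24:
            raise ValueError("sleep period must be shorter than 24 h")

    @property
    def duration_h(self) -> float:
        return float((self.wake - self.onset) / np.timedelta64(1, "h"))


@dataclass
class DayWindow:
    """One full day window: a waking period plus its following sleep period."""

    wake_time: np.datetime64
    onset_time: np.datetime64
    next_wake: np.datetime64
    wear_frac_wake: float = field(default=np.nan)
    wear_frac_sleep: float = field(default=np.nan)
    valid: bool = False

    def __post_init__(self) -> None:
        self.wake_time = _as_dt64(self.wake_time)
        self.onset_time = _as_dt64(self.onset_time)
        self.next_wake = _as_dt64(self.next_wake)
        if not (self.wake_time < self.onset_time < self.next_wake):
            raise ValueError("require wake_time < onset_time < next_wake")

    @property
    def waking_h(self) -> float:
        return float((self.onset_time - self.wake_time) / np.timedelta64(1, "h"))

    @property
    def sleep_h(self) -> float:
        return float((self.next_wake - self.onset_time) / np.timedelta64(1, "h"))
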