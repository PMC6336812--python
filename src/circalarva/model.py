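"""Shared domain types for the larval-zebrafish circadian analysis pipeline.

Time conventions
----------------
Internal behavioral time is measured in **seconds from recording start**.
Circadian phase is referenced to **light onset**: ``ActivityTrack.t0_s`` gives
the recording start time relative to light onset, so
``time_after_light_onset = recording_time + t0_s``.  In the study design the
recording starts at light onset, i.e. ``t0_s = 0`` and the light pulse occupies
the first 3 h or 12 h of the record.

Cell traces and expression courses are sampled in **hours**; expression time
is hours after light onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CircalarvaError",
    "SchemaError",
    "ParseError",
    "ArrhythmicCellError",
    "DegenerateSeriesError",
    "GENOTYPES",
    "SCHEDULE_LABELS",
    "CONDITIONS",
    "LightSchedule",
    "ActivityTrack",
    "CellTrace",
    "ExpressionCourse",
    "AnalysisConfig",
]


class CircalarvaError(Exception):
    """Base class for pipeline errors."""


class SchemaError(CircalarvaError):
    """A required column or field is missing or mislabeled."""


class ParseError(CircalarvaError):
    """A table row could not be converted to a valid value."""


class ArrhythmicCellError(CircalarvaError):
    """A cell failed the zero-amplitude rhythmicity test; phase is undefined."""


class DegenerateSeriesError(CircalarvaError):
    """A series has no variance or a degenerate design; statistic undefined."""


GENOTYPES = ("WT", "Cry1aKO", "Per2KO", "DKO", "TKO", "custom")
SCHEDULE_LABELS = ("DD", "pulse_3h", "pulse_12h", "custom")
CONDITIONS = ("dark", "light_12h")

_H = 3600.0


@dataclass(frozen=True)
class LightSchedule:
    """Light intervals of a recording, in seconds from recording start.

    ``intervals`` is an ordered tuple of ``(on_s, off_s)`` pairs.  Constant
    darkness (DD) has no intervals.
    """

    intervals: tuple[tuple[float, float], ...] = ()
    label: str = "DD"

    def __post_init__(self) -> None:
        if self.label not in SCHEDULE_LABELS:
            raise ValueError(f"unknown schedule label {self.label!r}")
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        prev_off = -np.inf
        for on, off in ivs:
            if not off > on:
                raise ValueError(f"light interval off ({off}) must exceed on ({on})")
            if on < prev_off:
                raise ValueError("light intervals must be non-overlapping and increasing")
            prev_off = off
        if self.label == "DD" and ivs:
            raise ValueError("DD schedule must have no light intervals")

    @classmethod
    def dd(cls) -> "LightSchedule":
        return cls((), "DD")

    @classmethod
    def pulse(cls, hours: float, start_s: float = 0.0) -> "LightSchedule":
        """Single light pulse of ``hours`` starting at ``start_s``."""
        label = {3.0: "pulse_3h", 12.0: "pulse_12h"}.get(float(hours), "custom")
        return cls(((start_s, start_s + hours * _H),), label)

    @property
    def pulse_end_s(self) -> float:
        """End of the last light interval (0 for DD)."""
        return self.intervals[-1][1] if self.intervals else 0.0

    def is_light(self, t_s: float) -> bool:
        return any(on <= t_s < off for on, off in self.intervals)


@dataclass
class ActivityTrack:
    """One animal's distance-moved-per-bin time series.

    1-s bins feed the bout analysis; 10-min bins feed actograms and the
    chi-square periodogram (see :func:`circalarva.rhythm.rebin_activity`).
    """

    animal_id: str
    genotype: str
    bin_width_s: float
    distances_mm: np.ndarray
    schedule: LightSchedule = field(default_factory=LightSchedule.dd)
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if not self.bin_width_s > 0:
            raise ValueError("bin_width_s must be positive")
        d = np.asarray(self.distances_mm, dtype=float)
        if d.ndim != 1 or d.size < 1:
            raise ValueError("distances_mm must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        self.distances_mm = d

    @property
    def n_bins(self) -> int:
        return int(self.distances_mm.size)

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_width_s

    @property
    def times_s(self) -> np.ndarray:
        """Start time of each bin, seconds from recording start."""
        return np.arange(self.n_bins) * self.bin_width_s

    def slice_seconds(self, start_s: float, stop_s: float) -> "ActivityTrack":
        """Sub-track covering ``[start_s, stop_s)`` (bin-aligned, inclusive of
        bins starting inside the window)."""
        if not 0 <= start_s < stop_s <= self.duration_s + 1e-9:
            raise ValueError("slice window outside track extent")
        i0 = int(np.ceil(start_s / self.bin_width_s - 1e-9))
        i1 = int(np.floor(stop_s / self.bin_width_s + 1e-9))
        if i1 <= i0:
            raise ValueError("empty slice window")
        return replace(
            self,
            distances_mm=self.distances_mm[i0:i1].copy(),
            t0_s=self.t0_s + i0 * self.bin_width_s,
        )


@dataclass
class CellTrace:
    """Single-cell bioluminescence time series (arbitrary intensity units)."""

    cell_id: str
    condition: str
    times_h: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        t = np.asarray(self.times_h, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape or t.ndim != 1 or t.size < 1:
            raise ValueError("times and intensities must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        self.times_h = t
        self.intensities = y

    @property
    def duration_h(self) -> float:
        return float(self.times_h[-1] - self.times_h[0])


@dataclass
class ExpressionCourse:
    """Relative expression of one gene at timepoints after light onset.

    Values are normalized so the earliest timepoint equals 1 (fold change
    relative to time 0), mirroring standard qPCR time-course presentation.
    """

    gene: str
    times_h: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or t.size < 1:
            raise ValueError("times and values must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("relative expression values must be positive")
        if abs(v[0] - 1.0) > 1e-6:
            raise ValueError("value at the earliest timepoint must be normalized to 1")
        self.times_h = t
        self.values = v

    @classmethod
    def from_raw(cls, gene: str, times_h: Sequence[float], raw: Sequence[float]) -> "ExpressionCourse":
        """Build a course from raw values, normalizing by the value at the
        earliest timepoint."""
        raw = np.asarray(raw, dtype=float)
        if raw.size == 0 or raw[0] <= 0:
            raise ValueError("raw value at time 0 must be positive")
        return cls(gene, np.asarray(times_h, dtype=float), raw / raw[0])


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters shared across pipeline stages.

    movement_epsilon_mm : distance above which a 1-s bin counts as active.
    rest_threshold_s    : minimum immobile-bout length scored as rest (sleep-like).
    periodogram_period_range_h : scanned period band of the periodogram.
    alpha               : significance level for rhythmicity / zero-amplitude tests.
    activity_window_days: (start_day, end_day) analysis window, days from light onset.
    rng_seed            : root seed for all simulated inputs.
    """

    movement_epsilon_mm: float = 0.0
    rest_threshold_s: float = 60.0
    periodogram_period_range_h: tuple[float, float] = (16.0, 32.0)
    circadian_band_h: tuple[float, float] = (20.0, 28.0)
    alpha: float = 0.05
    activity_window_days: tuple[float, float] = (1.0, 3.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.movement_epsilon_mm < 0:
            raise ValueError("movement_epsilon_mm must be >= 0")
        if not self.rest_threshold_s > 0:
            raise ValueError("rest_threshold_s must be positive")
        for name in ("periodogram_period_range_h", "circadian_band_h", "activity_window_days"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: min must be < max")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "movement_epsilon_mm": self.movement_epsilon_mm,
            "rest_threshold_s": self.rest_threshold_s,
            "periodogram_period_range_h": list(self.periodogram_period_range_h),
            "circadian_band_h": list(self.circadian_band_h),
            "alpha": self.alpha,
            "activity_window_days": list(self.activity_window_days),
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kw = dict(d)
        for name in ("periodogram_period_range_h", "circadian_band_h", "activity_window_days"):
            if name in kw:
                kw[name] = tuple(kw[name])
        return cls(**kw)
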