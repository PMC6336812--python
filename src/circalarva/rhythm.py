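"""Actograms and chi-square periodogram rhythmicity detection.

Activity is re-binned to 10-min totals, folded at candidate periods, and the
Sokolove–Bushell chi-square statistic

    Q_P = N * sum_h n_h (M_h - Mbar)^2 / sum_i (x_i - Mbar)^2

is referenced to a chi-square distribution with P - 1 degrees of freedom
(M_h: column means of the series folded at P bins, n_h: column occupancies,
N: total bins).  In the balanced case (n_h = K complete cycles) this is the
classical K*N*sum(M_h - Mbar)^2 / SS form.  Significance is Bonferroni
corrected across the scanned periods; an animal is called rhythmic when the
periodogram peak clears its threshold inside the circadian band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import lombscargle

from .model import ActivityTrack, CircalarvaError, DegenerateSeriesError

__all__ = [
    "Actogram",
    "PeriodogramResult",
    "RhythmCall",
    "rebin_activity",
    "build_actogram",
    "chi_square_periodogram",
    "lomb_scargle_periodogram",
    "classify_rhythmic",
    "rhythmic_ratio",
]

DAY_S = 86400.0
BINS_PER_DAY_10MIN = 144


@dataclass
class Actogram:
    """Daily raster of activity; rows are 24-h days of 10-min bins, doubled
    rows concatenate day d with day d+1 (zero-padded past the record end)."""

    day_rows: np.ndarray
    doubled: bool
    animal_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin_{j}" for j in range(self.day_rows.shape[1])]
        df = pd.DataFrame(self.day_rows, columns=cols)
        df.insert(0, "day", np.arange(self.day_rows.shape[0]))
        return df


@dataclass
class PeriodogramResult:
    periods_h: np.ndarray
    Qp: np.ndarray
    threshold: np.ndarray  # Bonferroni-corrected chi-square quantile per period
    peak_period_h: float
    peak_Qp: float
    peak_threshold: float
    animal_id: str = ""


@dataclass
class RhythmCall:
    animal_id: str
    is_rhythmic: bool
    peak_period_h: float
    excess: float  # peak_Qp - threshold at the peak


def rebin_activity(track: ActivityTrack, bin_width_s: float = 600.0) -> ActivityTrack:
    """Sum distances into wider bins (default 10 min); totals are conserved.

    The target width must be an integer multiple of the source width and the
    track length an integer number of target bins.
    """
    factor = bin_width_s / track.bin_width_s
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise CircalarvaError(
            f"target bin width {bin_width_s} is not an integer multiple of "
            f"source width {track.bin_width_s}"
        )
    factor = int(round(factor))
    n = track.n_bins
    if n % factor:
        raise CircalarvaError(
            f"track length {n} bins is not divisible by the re-binning factor {factor}; "
            "slice the track to a whole number of target bins first"
        )
    summed = track.distances_mm.reshape(-1, factor).sum(axis=1)
    return replace(track, distances_mm=summed, bin_width_s=float(bin_width_s))


def build_actogram(track: ActivityTrack, doubled: bool = True) -> Actogram:
    """Arrange a 10-min-binned track into one row per 24-h day."""
    if not np.isclose(track.bin_width_s, 600.0):
        raise CircalarvaError("actograms are built from 10-min bins; rebin first")
    if track.duration_s < DAY_S:
        raise CircalarvaError("actogram requires at least one full day of data")
    n_days = int(np.ceil(track.n_bins / BINS_PER_DAY_10MIN))
    padded = np.zeros(n_days * BINS_PER_DAY_10MIN)
    padded[: track.n_bins] = track.distances_mm
    rows = padded.reshape(n_days, BINS_PER_DAY_10MIN)
    if doubled:
        nxt = np.vstack([rows[1:], np.zeros((1, BINS_PER_DAY_10MIN))])
        rows = np.hstack([rows, nxt])
    return Actogram(day_rows=rows, doubled=doubled, animal_id=track.animal_id)


def chi_square_periodogram(
    track: ActivityTrack,
    period_range_h: tuple[float, float] = (16.0, 32.0),
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Chi-square periodogram over candidate periods at whole-bin resolution.

    Periods are scanned at every whole number of bins inside
    ``period_range_h`` (10-min steps for 10-min bins).  The significance
    curve is the chi-square quantile at 1 - alpha/m with P_bins - 1 degrees
    of freedom, m being the number of scanned periods.
    """
    x = track.distances_mm
    bw_h = track.bin_width_s / 3600.0
    lo, hi = period_range_h
    p_min = int(np.ceil(lo / bw_h - 1e-9))
    p_max = int(np.floor(hi / bw_h + 1e-9))
    if p_max < p_min:
        raise CircalarvaError("no whole-bin periods inside the scan range")
    if track.duration_s < 2 * p_max * track.bin_width_s:
        raise CircalarvaError("series must span at least two maximal periods")
    ss_total = float(np.sum((x - x.mean()) ** 2))
    if ss_total <= 0:
        raise DegenerateSeriesError("zero-variance series: periodogram undefined")

    n = x.size
    p_bins = np.arange(p_min, p_max + 1)
    m = p_bins.size
    qp = np.empty(m)
    for j, p in enumerate(p_bins):
        col = np.arange(n) % p
        sums = np.bincount(col, weights=x, minlength=p)
        cnts = np.bincount(col, minlength=p)
        means = sums / cnts
        qp[j] = n * float(np.sum(cnts * (means - x.mean()) ** 2)) / ss_total
    threshold = stats.chi2.ppf(1.0 - alpha / m, df=p_bins - 1)
    periods_h = p_bins * bw_h
    peak = int(np.argmax(qp))
    return PeriodogramResult(
        periods_h=periods_h,
        Qp=qp,
        threshold=threshold,
        peak_period_h=float(periods_h[peak]),
        peak_Qp=float(qp[peak]),
        peak_threshold=float(threshold[peak]),
        animal_id=track.animal_id,
    )


def lomb_scargle_periodogram(
    track: ActivityTrack,
    period_range_h: tuple[float, float] = (16.0, 32.0),
    n_periods: int = 97,
) -> pd.DataFrame:
    """Normalized Lomb-Scargle power over the same period band (alternative
    statistic; no significance curve is attached)."""
    t_h = track.times_s / 3600.0
    x = track.distances_mm - track.distances_mm.mean()
    if np.allclose(x, 0):
        raise DegenerateSeriesError("zero-variance series")
    periods = np.linspace(period_range_h[0], period_range_h[1], n_periods)
    power = lombscargle(t_h, x, 2 * np.pi / periods, normalize=True)
    return pd.DataFrame({"period_h": periods, "power": power})


def classify_rhythmic(
    result: PeriodogramResult,
    circadian_band_h: tuple[float, float] = (20.0, 28.0),
) -> RhythmCall:
    """Call an animal rhythmic when the periodogram peak is significant and
    falls inside the circadian band."""
    in_band = circadian_band_h[0] <= result.peak_period_h <= circadian_band_h[1]
    significant = result.peak_Qp > result.peak_threshold
    return RhythmCall(
        animal_id=result.animal_id,
        is_rhythmic=bool(significant and in_band),
        peak_period_h=result.peak_period_h,
        excess=float(result.peak_Qp - result.peak_threshold),
    )


def rhythmic_ratio(calls: pd.DataFrame | Sequence[RhythmCall]) -> pd.DataFrame:
    """Percentage of rhythmic animals per genotype x condition group.

    ``calls`` is either a DataFrame with columns ``genotype``, ``condition``
    and ``is_rhythmic`` or a sequence of :class:`RhythmCall` (then a single
    unlabeled group).  Percentages are reported both raw and rounded to the
    nearest integer.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame(
            {
                "genotype": "all",
                "condition": "all",
                "is_rhythmic": [c.is_rhythmic for c in calls],
            }
        )
    if calls.empty:
        raise CircalarvaError("rhythmic_ratio requires at least one call per group")
    grouped = calls.groupby(["genotype", "condition"], sort=False)
    out = grouped["is_rhythmic"].agg(n_total="count", n_rhythmic="sum").reset_index()
    out["percent_rhythmic"] = 100.0 * out["n_rhythmic"] / out["n_total"]
    out["percent_rhythmic_int"] = out["percent_rhythmic"].round().astype(int)
    return out
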