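"""Bout segmentation and sleep-architecture statistics for 1-s locomotor tracks.

A 1-s bin is *active* when its recorded distance exceeds a small threshold
ε (default 0: any detectable movement).  Maximal runs of same-state bins are
*active bouts* and *immobile bouts*.  An immobile bout of length ≥ θ (default
60 s) is a *rest bout*, the larval sleep-like state; *active periods* are the
maximal intervals free of rest bouts, with sub-threshold pauses absorbed.

The rest threshold itself can be estimated from the pooled immobile-bout
length distribution: on log-log axes the survival curve (1 − ECDF) of bout
lengths shows a slope break where brief within-activity pauses give way to
consolidated rest, and a two-segment continuous broken-line fit locates it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ActivityTrack, CircalarvaError

__all__ = [
    "BoutTable",
    "EcdfCurve",
    "ThresholdEstimate",
    "RestActivityStats",
    "classify_bins",
    "segment_bouts",
    "bout_table",
    "bout_ecdf",
    "pooled_bout_ecdf",
    "estimate_rest_threshold",
    "compute_rest_stats",
    "total_activity",
]

ACTIVE = "active"
IMMOBILE = "immobile"


@dataclass
class BoutTable:
    """Alternating run-length segmentation of one track.

    Parallel arrays over bouts; states strictly alternate, durations tile the
    track exactly, and immobile bouts carry zero distance.
    """

    track_ref: str
    states: np.ndarray  # str array of "active"/"immobile"
    start_s: np.ndarray
    duration_s: np.ndarray
    distance_mm: np.ndarray

    @property
    def n_bouts(self) -> int:
        return int(self.states.size)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def total_duration_s(self) -> float:
        return float(self.duration_s.sum())

    def lengths(self, state: str) -> np.ndarray:
        return self.duration_s[self.states == state]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_ref": self.track_ref,
                "state": self.states,
                "start_s": self.start_s,
                "duration_s": self.duration_s,
                "distance_mm": self.distance_mm,
            }
        )


@dataclass
class EcdfCurve:
    """Empirical cumulative distribution of pooled bout lengths."""

    lengths_s: np.ndarray  # sorted unique lengths
    cum_prob: np.ndarray  # non-decreasing, last value 1
    counts: np.ndarray  # observations at each unique length
    n: int  # total pooled bouts

    def survival(self) -> np.ndarray:
        return 1.0 - self.cum_prob


@dataclass
class ThresholdEstimate:
    """Changepoint of the immobile-bout log-log survival curve."""

    threshold_s: float
    fit_quality: float  # fractional SSE improvement of 2 segments over 1
    valid: bool


@dataclass
class RestActivityStats:
    """Per-animal rest/activity architecture over one analysis window."""

    animal_id: str
    resting_time_h_per_day: float
    n_active_rest_cycles: int
    mean_distance_per_active_period_mm: float  # NaN when no complete period
    mean_active_period_length_h: float  # NaN when no complete period
    window_s: tuple[float, float] = (0.0, 0.0)


def classify_bins(track: ActivityTrack, epsilon_mm: float = 0.0) -> np.ndarray:
    """Classify each 1-s bin as active (distance > ε) or immobile.

    Returns a boolean array, True = active.  Defined only on 1-s bins.
    """
    if not np.isclose(track.bin_width_s, 1.0):
        raise CircalarvaError(
            f"bout analysis is defined on 1-s bins (got {track.bin_width_s} s)"
        )
    if epsilon_mm < 0:
        raise ValueError("epsilon must be >= 0")
    return track.distances_mm > epsilon_mm


def segment_bouts(
    active: np.ndarray,
    bin_width_s: float,
    distances_mm: np.ndarray,
    track_ref: str = "",
) -> BoutTable:
    """Collapse a binary active/immobile sequence into maximal-run bouts.

    Per-bout distance is the sum over its bins (zero for immobile bouts by
    construction of the classification).
    """
    active = np.asarray(active, dtype=bool)
    if active.size == 0:
        raise CircalarvaError("cannot segment an empty sequence")
    distances_mm = np.asarray(distances_mm, dtype=float)
    if distances_mm.shape != active.shape:
        raise ValueError("distances and state sequence must have equal length")
    # run boundaries: indices where the state changes
    change = np.flatnonzero(np.diff(active.view(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [active.size]))
    states = np.where(active[starts], ACTIVE, IMMOBILE)
    dist = np.add.reduceat(distances_mm, starts)
    dist[states == IMMOBILE] = 0.0
    return BoutTable(
        track_ref=track_ref,
        states=states,
        start_s=starts * bin_width_s,
        duration_s=(ends - starts) * bin_width_s,
        distance_mm=dist,
    )


def bout_table(track: ActivityTrack, epsilon_mm: float = 0.0) -> BoutTable:
    """Classify and segment a 1-s track in one step."""
    act = classify_bins(track, epsilon_mm)
    return segment_bouts(act, track.bin_width_s, track.distances_mm, track.animal_id)


def bout_ecdf(lengths_s: Sequence[float]) -> EcdfCurve:
    """Empirical CDF over pooled bout lengths (pooling is the caller's concern)."""
    lengths = np.asarray(lengths_s, dtype=float)
    if lengths.size == 0:
        raise CircalarvaError("bout_ecdf requires at least one bout length")
    uniq, counts = np.unique(lengths, return_counts=True)
    cum = np.cumsum(counts) / lengths.size
    return EcdfCurve(lengths_s=uniq, cum_prob=cum, counts=counts, n=int(lengths.size))


def pooled_bout_ecdf(tables: Sequence[BoutTable], state: str = IMMOBILE) -> EcdfCurve:
    """ECDF of bout lengths of one state pooled across animals (one genotype)."""
    pooled = np.concatenate([bt.lengths(state) for bt in tables]) if tables else np.array([])
    return bout_ecdf(pooled)


def _broken_line_sse(x: np.ndarray, y: np.ndarray, xb: float) -> float:
    """SSE of the continuous two-segment least-squares line broken at xb."""
    design = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - xb)])
    _, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3 or res.size == 0:
        fit = design @ np.linalg.lstsq(design, y, rcond=None)[0]
        return float(np.sum((y - fit) ** 2))
    return float(res[0])


def estimate_rest_threshold(
    ecdf: EcdfCurve,
    min_improvement: float = 0.2,
    min_tail_count: int = 5,
) -> ThresholdEstimate:
    """Locate the slope break of the log10-survival vs log10-length curve.

    Fits a continuous two-segment broken line by exhaustive search over
    candidate breakpoints at observed lengths, minimizing total squared
    residual.  The estimate is flagged invalid when the broken line fails to
    improve the residual by at least ``min_improvement`` (default 20%) over
    the better of a single straight line and a smooth cubic of the same
    parameter count — a distribution with gradual curvature but no slope
    break (e.g. a single exponential, which is curved on log-log axes) is
    fit as well by the cubic, so no crossover is claimed.

    Points in the extreme tail supported by fewer than ``min_tail_count``
    exceeding observations are excluded from the fit: their log-survival
    values are dominated by sampling noise.
    """
    surv = ecdf.survival()
    keep = surv >= min_tail_count / ecdf.n
    x_all = ecdf.lengths_s[keep]
    s_all = surv[keep]
    pos = (s_all > 0) & (x_all > 0)
    x = np.log10(x_all[pos])
    y = np.log10(s_all[pos])
    if np.unique(x).size < 50 or (x.max() - x.min()) < 1.0:
        raise CircalarvaError(
            "need >= 50 distinct bout lengths spanning at least one decade; "
            "use the default 60 s rest threshold instead"
        )
    # smooth baselines: straight line and cubic (same df as the broken line)
    d1 = np.column_stack([np.ones_like(x), x])
    beta1, _, _, _ = np.linalg.lstsq(d1, y, rcond=None)
    sse1 = float(np.sum((y - d1 @ beta1) ** 2))
    d3 = np.column_stack([np.ones_like(x), x, x**2, x**3])
    beta3, _, _, _ = np.linalg.lstsq(d3, y, rcond=None)
    sse_smooth = min(sse1, float(np.sum((y - d3 @ beta3) ** 2)))
    # candidate breakpoints: interior observed lengths (>= 3 points per side)
    candidates = x[3:-3]
    if candidates.size == 0:
        raise CircalarvaError("too few interior points for a breakpoint search")
    sses = np.array([_broken_line_sse(x, y, xb) for xb in candidates])
    best = int(np.argmin(sses))
    improvement = 1.0 - sses[best] / sse_smooth if sse_smooth > 0 else 0.0
    valid = bool(improvement >= min_improvement)
    return ThresholdEstimate(
        threshold_s=float(10 ** candidates[best]),
        fit_quality=float(improvement),
        valid=valid,
    )


def compute_rest_stats(
    bouts: BoutTable,
    rest_threshold_s: float = 60.0,
    window_s: tuple[float, float] | None = None,
) -> RestActivityStats:
    """Rest/activity summary over an analysis window.

    Definitions (documented choices):

    * rest bout: immobile bout with full duration ≥ θ;
    * active period: maximal window interval containing no rest bout —
      short immobile pauses are absorbed;
    * resting time, expressed per 24-h day: Σ in-window rest durations
      × 24 / window length (boundary rest bouts clipped to the window);
    * active-rest cycles: rest bouts lying entirely inside the window;
    * per-period means: only over active periods whose extent is not cut by
      the window edge within the track (censored periods bias means).
    """
    if not rest_threshold_s > 0:
        raise ValueError("rest_threshold_s must be positive")
    track_start = float(bouts.start_s[0])
    track_end = float(bouts.end_s[-1])
    if window_s is None:
        window_s = (track_start, track_end)
    w0, w1 = map(float, window_s)
    if not (track_start - 1e-9 <= w0 < w1 <= track_end + 1e-9):
        raise CircalarvaError("window outside track extent")
    if (w1 - w0) < rest_threshold_s:
        raise CircalarvaError("window shorter than the rest threshold")

    starts, ends = bouts.start_s, bouts.end_s
    is_rest = (bouts.states == IMMOBILE) & (bouts.duration_s >= rest_threshold_s)
    overlaps = (ends > w0) & (starts < w1)

    rest_idx = np.flatnonzero(is_rest & overlaps)
    rest_clip_lo = np.maximum(starts[rest_idx], w0)
    rest_clip_hi = np.minimum(ends[rest_idx], w1)
    resting_s = float(np.sum(rest_clip_hi - rest_clip_lo))
    n_cycles = int(np.sum((starts[rest_idx] >= w0 - 1e-9) & (ends[rest_idx] <= w1 + 1e-9)))

    # active periods: complement of clipped rest intervals within the window
    period_bounds = [w0]
    for lo, hi in zip(rest_clip_lo, rest_clip_hi):
        period_bounds.extend((lo, hi))
    period_bounds.append(w1)
    periods = [
        (period_bounds[i], period_bounds[i + 1])
        for i in range(0, len(period_bounds), 2)
        if period_bounds[i + 1] - period_bounds[i] > 1e-9
    ]

    rest_starts_all = starts[is_rest]
    rest_ends_all = ends[is_rest]
    lengths, dists = [], []
    for lo, hi in periods:
        # censored: the period is cut by the window edge while the track
        # (and hence the period) continues beyond it
        cut_left = (
            abs(lo - w0) < 1e-9
            and w0 > track_start + 1e-9
            and not np.any(np.isclose(rest_ends_all, w0))
        )
        cut_right = (
            abs(hi - w1) < 1e-9
            and w1 < track_end - 1e-9
            and not np.any(np.isclose(rest_starts_all, w1))
        )
        if cut_left or cut_right:
            continue
        lengths.append(hi - lo)
        inside = (bouts.states == ACTIVE) & (starts >= lo - 1e-9) & (ends <= hi + 1e-9)
        dists.append(float(bouts.distance_mm[inside].sum()))

    window_len = w1 - w0
    return RestActivityStats(
        animal_id=bouts.track_ref,
        resting_time_h_per_day=resting_s / window_len * 24.0,
        n_active_rest_cycles=n_cycles,
        mean_distance_per_active_period_mm=float(np.mean(dists)) if dists else float("nan"),
        mean_active_period_length_h=float(np.mean(lengths)) / 3600.0 if lengths else float("nan"),
        window_s=(w0, w1),
    )


def total_activity(track: ActivityTrack, window_days: tuple[float, float]) -> float:
    """Total distance moved (mm) over a window given in days from recording
    start.  Invariant to re-binning because it sums raw per-bin distances."""
    d0, d1 = window_days
    w0, w1 = d0 * 86400.0, d1 * 86400.0
    if not (0 <= w0 < w1 <= track.duration_s + 1e-9):
        raise CircalarvaError("activity window outside track extent")
    t = track.times_s
    sel = (t >= w0 - 1e-9) & (t < w1 - 1e-9)
    if not np.any(sel):
        raise CircalarvaError("empty activity window")
    return float(track.distances_mm[sel].sum())
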