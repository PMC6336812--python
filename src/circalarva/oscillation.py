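"""Cosinor fitting, trace conditioning and circular phase-synchronization stats.

The single-component cosinor model is

    y(t) = M + A cos(2 pi (t - phi) / tau)
         = M + beta cos(2 pi t / tau) + gamma sin(2 pi t / tau),

fit by ordinary least squares; A = sqrt(beta^2 + gamma^2) and the acrophase
phi = (tau / 2 pi) atan2(gamma, beta) mod tau is the time (hours after light
onset) at which the fitted cosine peaks.  Rhythmicity is the zero-amplitude
F-test with (2, n - 3) degrees of freedom.

Per-cell phases phi are mapped to angles 2 pi phi / tau and summarized by the
resultant vector: mean phase arg(sum e^{i phi}), resultant length
R = |sum e^{i phi}| / n, and the Rayleigh uniformity test using Zar's
approximation p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)) with Rn = nR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ArrhythmicCellError, CellTrace, CircalarvaError, DegenerateSeriesError

__all__ = [
    "CosinorFit",
    "PhaseSample",
    "CircularSummary",
    "detrend_trace",
    "normalize_trace",
    "fit_cosinor",
    "fit_cosinor_scan",
    "extract_phase",
    "circular_summary",
    "rayleigh_p",
]


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float  # >= 0
    acrophase_h: float  # in [0, period_h)
    period_h: float
    p_zero_amplitude: float
    rss: float
    n: int

    def predict(self, times_h: np.ndarray) -> np.ndarray:
        w = 2 * np.pi / self.period_h
        return self.mesor + self.amplitude * np.cos(w * (np.asarray(times_h) - self.acrophase_h))


@dataclass
class PhaseSample:
    cell_id: str
    phase_rad: float  # in [0, 2 pi)
    acrophase_h: float
    p_zero_amplitude: float


@dataclass
class CircularSummary:
    n: int
    mean_phase_rad: float
    resultant_length: float  # R in [0, 1]
    rayleigh_p: float
    histogram: np.ndarray  # counts per angular bin, bins start at 0
    bin_edges_rad: np.ndarray


def detrend_trace(trace: CellTrace, window_h: float = 24.0) -> CellTrace:
    """Subtract a centered moving average (deviation-from-moving-average
    detrend); edge windows shrink to one-sided."""
    if trace.duration_h < window_h:
        raise CircalarvaError("trace shorter than the detrending window")
    dt = np.diff(trace.times_h)
    if not np.allclose(dt, dt[0], rtol=1e-3):
        raise CircalarvaError("detrending assumes approximately uniform sampling")
    half = int(round(window_h / dt[0] / 2))
    s = pd.Series(trace.intensities)
    ma = s.rolling(window=2 * half + 1, center=True, min_periods=1).mean().to_numpy()
    return replace(trace, intensities=trace.intensities - ma)


def normalize_trace(trace: CellTrace, mode: str = "mean") -> CellTrace:
    """Scale a trace by its time-mean absolute intensity (``mean``) or its
    maximum circadian peak (``max_peak``)."""
    if mode == "mean":
        div = float(np.mean(np.abs(trace.intensities)))
    elif mode == "max_peak":
        div = float(np.max(trace.intensities))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if div == 0:
        raise CircalarvaError(f"zero divisor in {mode!r} normalization")
    return replace(trace, intensities=trace.intensities / div)


def fit_cosinor(
    times_h: Sequence[float],
    values: Sequence[float],
    period_h: float = 24.0,
) -> CosinorFit:
    """Least-squares single-component cosinor fit at fixed period."""
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise CircalarvaError("cosinor needs at least 4 samples")
    if t.max() - t.min() < period_h:
        raise CircalarvaError("samples must span at least one full period")
    w = 2 * np.pi / period_h
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateSeriesError("degenerate cosinor design (times aliased mod period)")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    mesor, beta, gamma = coef
    resid = y - design @ coef
    rss = float(resid @ resid)
    amplitude = float(np.hypot(beta, gamma))
    acrophase = float((period_h / (2 * np.pi)) * np.arctan2(gamma, beta) % period_h)
    if period_h - acrophase < 1e-9:  # wrap t = tau - eps to 0
        acrophase = 0.0
    # zero-amplitude F-test against the mesor-only model
    rss0 = float(np.sum((y - y.mean()) ** 2))
    n = t.size
    df2 = n - 3
    if df2 <= 0 or rss <= 0:
        p = 0.0 if rss0 > rss else 1.0
    else:
        f = ((rss0 - rss) / 2.0) / (rss / df2)
        p = float(stats.f.sf(f, 2, df2))
    return CosinorFit(
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase_h=acrophase,
        period_h=float(period_h),
        p_zero_amplitude=p,
        rss=rss,
        n=n,
    )


def fit_cosinor_scan(
    times_h: Sequence[float],
    values: Sequence[float],
    period_grid_h: Sequence[float],
) -> CosinorFit:
    """Free-period variant: fit at every grid period, keep the lowest RSS."""
    fits = [fit_cosinor(times_h, values, p) for p in period_grid_h]
    return min(fits, key=lambda f: f.rss)


def extract_phase(trace: CellTrace, period_h: float = 24.0, alpha: float = 0.05) -> PhaseSample:
    """Circular phase of one (detrended, normalized) cell from its cosinor
    acrophase: phase = 2 pi phi / tau.

    Raises :class:`ArrhythmicCellError` when the zero-amplitude test is not
    rejected at ``alpha``; callers must exclude (and report) such cells.
    """
    fit = fit_cosinor(trace.times_h, trace.intensities, period_h)
    if fit.p_zero_amplitude >= alpha:
        raise ArrhythmicCellError(
            f"cell {trace.cell_id!r}: zero-amplitude p = {fit.p_zero_amplitude:.3g} >= {alpha}"
        )
    phase = float(2 * np.pi * fit.acrophase_h / period_h) % (2 * np.pi)
    if 2 * np.pi - phase < 1e-9:
        phase = 0.0
    return PhaseSample(
        cell_id=trace.cell_id,
        phase_rad=phase,
        acrophase_h=fit.acrophase_h,
        p_zero_amplitude=fit.p_zero_amplitude,
    )


def rayleigh_p(n: int, R: float) -> float:
    """Rayleigh uniformity p-value (Zar's approximation), clipped to [0, 1]."""
    rn = n * R
    p = np.exp(np.sqrt(1.0 + 4 * n + 4.0 * (n * n - rn * rn)) - (1.0 + 2 * n))
    return float(min(max(p, 0.0), 1.0))


def circular_summary(
    phases: Sequence[PhaseSample] | Sequence[float] | np.ndarray,
    n_bins: int = 12,
) -> CircularSummary:
    """Mean phase, resultant length, Rayleigh test and circular histogram."""
    if len(phases) and isinstance(phases[0], PhaseSample):
        angles = np.array([p.phase_rad for p in phases], dtype=float)
    else:
        angles = np.asarray(phases, dtype=float)
    n = angles.size
    if n < 2:
        raise CircalarvaError("circular summary requires at least 2 phases")
    z = np.exp(1j * angles).sum()
    R = float(np.abs(z) / n)
    mean_phase = float(np.angle(z) % (2 * np.pi))
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    hist, _ = np.histogram(angles % (2 * np.pi), bins=edges)
    return CircularSummary(
        n=int(n),
        mean_phase_rad=mean_phase,
        resultant_length=R,
        rayleigh_p=rayleigh_p(n, R),
        histogram=hist,
        bin_edges_rad=edges,
    )
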