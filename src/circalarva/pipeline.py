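"""End-to-end behavior and imaging pipelines with reproducible manifests.

Behavior: 1-s tracks -> bin classification -> bout segmentation -> rest
statistics over the analysis window, and in parallel 10-min re-binning ->
chi-square periodogram over the post-pulse epoch -> rhythm call -> group
ratios.  Imaging: per-cell detrend -> normalize -> cosinor -> phase ->
circular summary per condition.  Per-animal/cell failures are quarantined
with a logged reason rather than aborting the cohort; output is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bouts import bout_table, compute_rest_stats, total_activity
from .model import (
    ActivityTrack,
    AnalysisConfig,
    ArrhythmicCellError,
    CellTrace,
    CircalarvaError,
    DegenerateSeriesError,
)
from .oscillation import circular_summary, detrend_trace, extract_phase, fit_cosinor, normalize_trace
from .rhythm import chi_square_periodogram, classify_rhythmic, rebin_activity, rhythmic_ratio

__all__ = ["BehaviorResult", "ImagingResult", "run_behavior_pipeline", "run_imaging_pipeline"]


@dataclass
class BehaviorResult:
    stats: pd.DataFrame  # per-animal rest/activity statistics
    calls: pd.DataFrame  # per-animal rhythm calls
    ratios: pd.DataFrame  # genotype x condition rhythmic percentages
    manifest: dict
    failures: list = field(default_factory=list)


@dataclass
class ImagingResult:
    fits: pd.DataFrame  # per-cell cosinor parameters
    phases: pd.DataFrame  # per-cell phases (rhythmic cells only)
    summaries: pd.DataFrame  # circular summary per condition
    excluded: pd.DataFrame  # arrhythmic cells with reasons
    manifest: dict


def _manifest(config: AnalysisConfig, input_ids: Sequence[str], counts: Mapping[str, int]) -> dict:
    return {
        "software_version": __version__,
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "input_ids": list(input_ids),
        "row_counts": dict(counts),
    }


def run_behavior_pipeline(
    tracks: Sequence[ActivityTrack],
    config: AnalysisConfig | None = None,
) -> BehaviorResult:
    """Run the full behavior analysis on a cohort of 1-s tracks.

    Rest statistics use ``config.activity_window_days`` (days from light
    onset); the periodogram runs on the post-pulse epoch re-binned to 10 min.
    A zero-variance (never-moving) animal still yields a stats row and an
    arrhythmic call; other per-animal errors are quarantined into
    ``failures``.
    """
    config = config or AnalysisConfig()
    if not tracks:
        raise CircalarvaError("behavior pipeline requires at least one track")
    stats_rows, call_rows, failures = [], [], []
    for tr in tracks:
        try:
            bt = bout_table(tr, config.movement_epsilon_mm)
            d0, d1 = config.activity_window_days
            w0 = d0 * 86400.0 - tr.t0_s
            w1 = d1 * 86400.0 - tr.t0_s
            st = compute_rest_stats(bt, config.rest_threshold_s, (w0, w1))
            stats_rows.append(
                {
                    "animal_id": tr.animal_id,
                    "genotype": tr.genotype,
                    "condition": tr.schedule.label,
                    "resting_time_h_per_day": st.resting_time_h_per_day,
                    "n_active_rest_cycles": st.n_active_rest_cycles,
                    "mean_distance_per_active_period_mm": st.mean_distance_per_active_period_mm,
                    "mean_active_period_length_h": st.mean_active_period_length_h,
                    "total_activity_mm": total_activity(tr, (d0 - tr.t0_s / 86400.0, d1 - tr.t0_s / 86400.0)),
                }
            )
        except CircalarvaError as exc:
            failures.append({"animal_id": tr.animal_id, "stage": "bouts", "reason": str(exc)})
            continue
        try:
            pulse_end = tr.schedule.pulse_end_s
            epoch_start = max(pulse_end - tr.t0_s, 0.0)
            # trim to a whole number of 10-min bins
            n_bins = int((tr.duration_s - epoch_start) // 600.0)
            sliced = tr.slice_seconds(epoch_start, epoch_start + n_bins * 600.0)
            binned = rebin_activity(sliced, 600.0)
            pg = chi_square_periodogram(binned, config.periodogram_period_range_h, config.alpha)
            call = classify_rhythmic(pg, config.circadian_band_h)
        except DegenerateSeriesError:
            call = None
        except CircalarvaError as exc:
            failures.append({"animal_id": tr.animal_id, "stage": "rhythm", "reason": str(exc)})
            continue
        call_rows.append(
            {
                "animal_id": tr.animal_id,
                "genotype": tr.genotype,
                "condition": tr.schedule.label,
                "is_rhythmic": call.is_rhythmic if call else False,
                "peak_period_h": call.peak_period_h if call else float("nan"),
                "excess": call.excess if call else float("nan"),
            }
        )
    if not stats_rows:
        raise CircalarvaError("no valid animals in the cohort")
    stats = pd.DataFrame(stats_rows)
    calls = pd.DataFrame(call_rows)
    ratios = rhythmic_ratio(calls) if not calls.empty else pd.DataFrame()
    manifest = _manifest(
        config,
        [tr.animal_id for tr in tracks],
        {"stats": len(stats), "calls": len(calls), "ratios": len(ratios), "failures": len(failures)},
    )
    return BehaviorResult(stats=stats, calls=calls, ratios=ratios, manifest=manifest, failures=failures)


def run_imaging_pipeline(
    traces: Sequence[CellTrace],
    config: AnalysisConfig | None = None,
    detrend_window_h: float = 24.0,
    period_h: float = 24.0,
    n_bins: int = 12,
) -> ImagingResult:
    """Detrend, normalize, cosinor-fit and phase-summarize cell traces.

    Conditions are summarized separately; arrhythmic cells (zero-amplitude
    test not rejected at ``config.alpha``) are excluded and listed.  A
    condition in which fewer than 2 cells are rhythmic is an error.
    """
    config = config or AnalysisConfig()
    if not traces:
        raise CircalarvaError("imaging pipeline requires at least one trace")
    fit_rows, phase_rows, excluded = [], [], []
    phases_by_cond: dict[str, list] = {}
    for tr in traces:
        try:
            conditioned = normalize_trace(detrend_trace(tr, detrend_window_h), "mean")
            fit = fit_cosinor(conditioned.times_h, conditioned.intensities, period_h)
            fit_rows.append(
                {
                    "cell_id": tr.cell_id,
                    "condition": tr.condition,
                    "mesor": fit.mesor,
                    "amplitude": fit.amplitude,
                    "acrophase_h": fit.acrophase_h,
                    "p_zero_amplitude": fit.p_zero_amplitude,
                }
            )
            ph = extract_phase(conditioned, period_h, config.alpha)
        except ArrhythmicCellError as exc:
            excluded.append({"cell_id": tr.cell_id, "condition": tr.condition, "reason": str(exc)})
            continue
        except (CircalarvaError, DegenerateSeriesError) as exc:
            excluded.append({"cell_id": tr.cell_id, "condition": tr.condition, "reason": str(exc)})
            continue
        phase_rows.append(
            {
                "cell_id": tr.cell_id,
                "condition": tr.condition,
                "phase_rad": ph.phase_rad,
                "acrophase_h": ph.acrophase_h,
            }
        )
        phases_by_cond.setdefault(tr.condition, []).append(ph.phase_rad)

    conditions = {tr.condition for tr in traces}
    summary_rows = []
    for cond in sorted(conditions):
        phases = phases_by_cond.get(cond, [])
        if len(phases) == 0:
            raise CircalarvaError(f"all cells arrhythmic in condition {cond!r}")
        if len(phases) < 2:
            raise CircalarvaError(
                f"condition {cond!r}: need >= 2 rhythmic cells for a circular summary"
            )
        cs = circular_summary(np.array(phases), n_bins=n_bins)
        summary_rows.append(
            {
                "condition": cond,
                "n": cs.n,
                "mean_phase_rad": cs.mean_phase_rad,
                "mean_phase_h": cs.mean_phase_rad * period_h / (2 * np.pi),
                "resultant_length": cs.resultant_length,
                "rayleigh_p": cs.rayleigh_p,
                **{f"hist_bin_{i}": int(c) for i, c in enumerate(cs.histogram)},
            }
        )
    fits = pd.DataFrame(fit_rows)
    phases_df = pd.DataFrame(phase_rows)
    summaries = pd.DataFrame(summary_rows)
    excluded_df = pd.DataFrame(excluded, columns=["cell_id", "condition", "reason"])
    manifest = _manifest(
        config,
        [tr.cell_id for tr in traces],
        {
            "fits": len(fits),
            "phases": len(phases_df),
            "summaries": len(summaries),
            "excluded": len(excluded_df),
        },
    )
    return ImagingResult(
        fits=fits, phases=phases_df, summaries=summaries, excluded=excluded_df, manifest=manifest
    )
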