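"""Synthetic locomotor tracks, single-cell oscillators and expression courses.

The behavior generator is an alternating-renewal process: active periods
(lognormal durations) alternate with rest bouts (lognormal, mass dominated by
>= 60 s).  Within an active period, 1-s distances are gamma draws interrupted
by brief exponential pauses (< 60 s).  A light pulse gates circadian control:
after the pulse ends, the rest-initiation hazard is modulated by
``1 + depth * cos(2 pi (t - phi_rest) / 24 h)``; without light (or for
genotypes whose cellular clocks stay out of phase) there is no modulation and
hence no behavioral rhythm.  Genotype presets encode the wild-type and the
clock double/triple-knockout phenotypes: resting time per day near 7.8 h (WT)
versus 20.5 / 20.6 h (DKO / TKO), and modulation depths ordered so that
rhythmicity follows WT(3h) > DKO(3h), DKO(12h) > DKO(3h), DKO(12h) > TKO(12h).

Cellular traces are damped noisy cosines with either uniformly random phases
(dark-kept cultures, desynchronized clocks) or a common phase with small
dispersion (light-synchronized cultures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import ActivityTrack, CellTrace, ExpressionCourse, LightSchedule

__all__ = [
    "GenotypePreset",
    "OscillatorParams",
    "SimulationSpec",
    "preset",
    "simulate_track",
    "simulate_cohort",
    "simulate_cells",
    "cell_params",
    "simulate_expression",
    "simulate_crossover_bouts",
    "simulate_bout_pool",
]

DAY_S = 86400.0
BEHAVIOR_ACROPHASE_H = 6.0  # activity peak mid-subjective-day after light onset
EXPRESSION_KINDS = ("acute_inducible", "slow_inducible", "clock_output", "flat")


@dataclass(frozen=True)
class SimulationSpec:
    """Shared simulation geometry; the seed fixes all outputs bit-for-bit."""

    n: int = 1
    duration_days: float = 4.0
    bin_width_s: float = 1.0
    sampling_interval_h: float = 0.5
    schedule: LightSchedule = field(default_factory=LightSchedule.dd)
    seed: int = 0


@dataclass(frozen=True)
class GenotypePreset:
    """Alternating-renewal parameters of one genotype.

    ``circadian_mod_depth`` maps a light-schedule label to the depth of the
    post-pulse rest-initiation modulation.  ``mean_active_period_h`` is
    calibrated (see :meth:`calibrated`) so the day-averaged expected resting
    time under a 12-h pulse matches the genotype's target.
    """

    name: str
    mean_rest_bout_s: float
    mean_active_period_h: float
    short_pause_rate_per_min: float = 2.0
    mean_short_pause_s: float = 2.0
    distance_per_active_s_mm: float = 0.36
    distance_dispersion: float = 0.6  # gamma shape of per-second distances
    rest_sigma_log: float = 0.55
    active_sigma_log: float = 0.7
    circadian_mod_depth: dict = field(
        default_factory=lambda: {"DD": 0.0, "pulse_3h": 0.0, "pulse_12h": 0.0, "custom": 0.0}
    )
    rest_initiation_rate_per_h: float = 0.0  # derived: 1 / mean active period

    def __post_init__(self) -> None:
        for f in (
            self.mean_rest_bout_s,
            self.mean_active_period_h,
            self.short_pause_rate_per_min,
            self.mean_short_pause_s,
            self.distance_per_active_s_mm,
            self.distance_dispersion,
        ):
            if not f > 0:
                raise ValueError("preset parameters must be positive")
        for d in self.circadian_mod_depth.values():
            if not 0 <= d <= 1:
                raise ValueError("modulation depth must be in [0, 1]")
        object.__setattr__(
            self, "rest_initiation_rate_per_h", 1.0 / self.mean_active_period_h
        )

    def mod_depth(self, schedule_label: str) -> float:
        return float(self.circadian_mod_depth.get(schedule_label, 0.0))

    def expected_resting_time_h(self, schedule_label: str = "pulse_12h") -> float:
        """Day-averaged expected resting time (h/day) under the quasi-static
        renewal model: rest fraction rho(u) = D_r m(u) / (D_r m(u) + D_a)."""
        d = self.mod_depth(schedule_label)
        u = np.linspace(0.0, 2 * np.pi, 2881)[:-1]
        m = 1.0 + d * np.cos(u)
        da = self.mean_active_period_h * 3600.0
        rho = self.mean_rest_bout_s * m / (self.mean_rest_bout_s * m + da)
        return float(24.0 * rho.mean())

    @classmethod
    def calibrated(
        cls,
        name: str,
        target_resting_h_per_day: float,
        mean_rest_bout_s: float,
        mod_depths: dict,
        **kwargs,
    ) -> "GenotypePreset":
        """Solve the mean active-period length so the expected resting time
        under a 12-h pulse equals the target."""
        from scipy.optimize import brentq

        d12 = float(mod_depths.get("pulse_12h", 0.0))
        u = np.linspace(0.0, 2 * np.pi, 2881)[:-1]
        m = 1.0 + d12 * np.cos(u)
        target_frac = target_resting_h_per_day / 24.0

        def gap(da_s: float) -> float:
            rho = mean_rest_bout_s * m / (mean_rest_bout_s * m + da_s)
            return float(rho.mean()) - target_frac

        da = brentq(gap, 1.0, 1e6)
        return cls(
            name=name,
            mean_rest_bout_s=mean_rest_bout_s,
            mean_active_period_h=da / 3600.0,
            circadian_mod_depth=dict(mod_depths),
            **kwargs,
        )

    @classmethod
    def from_rest_fraction(
        cls,
        rest_fraction: float,
        mean_rest_bout_s: float = 300.0,
        name: str = "custom",
        mod_depths: dict | None = None,
        **kwargs,
    ) -> "GenotypePreset":
        """Unmodulated preset with a prescribed mean resting fraction."""
        if not 0 < rest_fraction < 1:
            raise ValueError("rest_fraction must be in (0, 1)")
        da_s = mean_rest_bout_s * (1.0 - rest_fraction) / rest_fraction
        return cls(
            name=name,
            mean_rest_bout_s=mean_rest_bout_s,
            mean_active_period_h=da_s / 3600.0,
            circadian_mod_depth=dict(mod_depths or {}),
            **kwargs,
        )


def preset(name: str) -> GenotypePreset:
    """Genotype presets calibrated to the knockout-study phenotypes.

    Resting-time targets (h/day under a 12-h pulse): WT 7.8, DKO 20.5,
    TKO 20.6.  Modulation depths order the rhythmic ratios: WT high under
    either pulse; DKO near zero after 3 h but intermediate after 12 h;
    TKO near zero throughout.
    """
    if name == "WT":
        return GenotypePreset.calibrated(
            "WT",
            target_resting_h_per_day=7.8,
            mean_rest_bout_s=255.0,
            mod_depths={"DD": 0.0, "pulse_3h": 0.9, "pulse_12h": 0.9},
            distance_per_active_s_mm=0.36,
        )
    if name == "DKO":
        return GenotypePreset.calibrated(
            "DKO",
            target_resting_h_per_day=20.5,
            mean_rest_bout_s=417.0,
            mod_depths={"DD": 0.0, "pulse_3h": 0.03, "pulse_12h": 0.45},
            distance_per_active_s_mm=0.13,
        )
    if name == "TKO":
        return GenotypePreset.calibrated(
            "TKO",
            target_resting_h_per_day=20.6,
            mean_rest_bout_s=431.0,
            mod_depths={"DD": 0.0, "pulse_3h": 0.03, "pulse_12h": 0.03},
            distance_per_active_s_mm=0.086,
        )
    raise KeyError(f"no preset named {name!r} (choose WT, DKO or TKO)")


def _lognormal(rng: np.random.Generator, mean: float, sigma_log: float, size=None):
    mu = np.log(mean) - sigma_log**2 / 2.0
    return rng.lognormal(mu, sigma_log, size)


def simulate_track(
    preset: GenotypePreset,
    spec: SimulationSpec,
    phi0_h: float = BEHAVIOR_ACROPHASE_H,
) -> ActivityTrack:
    """Simulate one animal's 1-s distance track.

    ``phi0_h`` is the behavioral acrophase (hours after light onset at which
    activity peaks); the rest-initiation hazard therefore peaks 12 h later.
    Modulation applies only after the light pulse ends.
    """
    if not np.isclose(spec.bin_width_s, 1.0):
        raise ValueError("behavior tracks are simulated at 1-s bins")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_days * DAY_S))
    depth = preset.mod_depth(spec.schedule.label)
    pulse_end = spec.schedule.pulse_end_s
    phi_rest_h = (phi0_h + 12.0) % 24.0
    da_s = preset.mean_active_period_h * 3600.0

    def hazard_mult(t_s: float) -> float:
        if depth == 0.0 or t_s < pulse_end:
            return 1.0
        return 1.0 + depth * np.cos(2 * np.pi * ((t_s / 3600.0) - phi_rest_h) / 24.0)

    # alternating renewal event sequence
    is_active: list[bool] = []
    durations: list[int] = []
    p_active = da_s / (da_s + preset.mean_rest_bout_s)
    state_active = bool(rng.random() < p_active)
    t = 0.0
    while t < n:
        if state_active:
            exposure = _lognormal(rng, da_s, preset.active_sigma_log)
            dur = exposure
            for _ in range(3):  # quasi-static hazard: D = E / m(t + D/2)
                m = max(hazard_mult(t + dur / 2.0), 1e-3)
                dur = exposure / m
        else:
            dur = _lognormal(rng, preset.mean_rest_bout_s, preset.rest_sigma_log)
        dur = max(int(round(dur)), 1)
        is_active.append(state_active)
        durations.append(dur)
        t += dur
        state_active = not state_active

    states = np.repeat(np.array(is_active, dtype=bool), np.array(durations))[:n]

    # movement/pause microstructure within active time
    active_idx = np.flatnonzero(states)
    n_active = active_idx.size
    moving = np.ones(n_active, dtype=bool)
    if n_active and preset.short_pause_rate_per_min > 0:
        mean_run = 60.0 / preset.short_pause_rate_per_min
        runs: list[int] = []
        flags: list[bool] = []
        total = 0
        move = True
        while total < n_active:
            mean = mean_run if move else preset.mean_short_pause_s
            r = int(round(rng.exponential(mean)))
            r = max(min(r, 59) if not move else r, 1)
            runs.append(r)
            flags.append(move)
            total += r
            move = not move
        moving = np.repeat(np.array(flags, dtype=bool), np.array(runs))[:n_active]

    dist = np.zeros(n)
    move_idx = active_idx[moving]
    if move_idx.size:
        k = preset.distance_dispersion
        dist[move_idx] = rng.gamma(k, preset.distance_per_active_s_mm / k, move_idx.size)
    return ActivityTrack(
        animal_id=f"{preset.name}_{spec.seed}",
        genotype=preset.name if preset.name in ("WT", "DKO", "TKO") else "custom",
        bin_width_s=1.0,
        distances_mm=dist,
        schedule=spec.schedule,
        t0_s=0.0,
    )


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, np.uint32) >> np.uint32(1)


def simulate_cohort(
    preset: GenotypePreset,
    spec: SimulationSpec,
    phi0_h: float = BEHAVIOR_ACROPHASE_H,
) -> list[ActivityTrack]:
    """Simulate ``spec.n`` animals; each animal gets a child seed derived
    from ``spec.seed`` so the cohort is reproducible as a whole."""
    tracks = []
    for i, s in enumerate(_child_seeds(spec.seed, spec.n)):
        sub = SimulationSpec(
            n=1,
            duration_days=spec.duration_days,
            bin_width_s=spec.bin_width_s,
            schedule=spec.schedule,
            seed=int(s),
        )
        tr = simulate_track(preset, sub, phi0_h)
        tr.animal_id = f"{preset.name}_{spec.schedule.label}_{i:02d}"
        tracks.append(tr)
    return tracks


@dataclass(frozen=True)
class OscillatorParams:
    """Damped noisy cosine parameters for cultured-cell traces.

    ``phase_mode='uniform_random'`` models dark-kept cultures whose cellular
    clocks run but are out of phase; ``'common'`` models light-synchronized
    cultures (wrapped normal around ``common_phase_h``).
    """

    period_h: float = 24.0
    amplitude: float = 4.0
    baseline: float = 10.0
    damping_per_day: float = 0.1
    noise_sd: float = 0.3
    trend_slope_per_h: float = 0.0
    phase_mode: str = "uniform_random"
    common_phase_h: float = 6.0
    common_phase_sd_h: float = 1.0

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.damping_per_day < 1:
            raise ValueError("damping_per_day must be in [0, 1)")
        if self.phase_mode not in ("uniform_random", "common"):
            raise ValueError("phase_mode must be 'uniform_random' or 'common'")


def cell_params(condition: str, synchronizes: bool = True, **overrides) -> OscillatorParams:
    """Oscillator parameters for a culture condition.

    Dark-kept cells are desynchronized; a 12-h light pulse synchronizes the
    population only when the genotype's light-input pathway is intact
    (``synchronizes=False`` models the triple knockout).
    """
    mode = "common" if (condition == "light_12h" and synchronizes) else "uniform_random"
    return OscillatorParams(phase_mode=mode, **overrides)


def simulate_cells(
    params: OscillatorParams,
    spec: SimulationSpec,
    condition: str = "dark",
) -> list[CellTrace]:
    """Simulate ``spec.n`` single-cell bioluminescence traces:

    I(t) = baseline (1 + slope t) + A (1 - damping)^{t/24} cos(2 pi (t - phi)/tau) + noise
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.duration_days * 24.0 + 1e-9, spec.sampling_interval_h)
    traces = []
    for i in range(spec.n):
        if params.phase_mode == "uniform_random":
            phi = rng.uniform(0.0, params.period_h)
        else:
            phi = rng.normal(params.common_phase_h, params.common_phase_sd_h) % params.period_h
        envelope = params.amplitude * (1.0 - params.damping_per_day) ** (times / 24.0)
        y = (
            params.baseline * (1.0 + params.trend_slope_per_h * times)
            + envelope * np.cos(2 * np.pi * (times - phi) / params.period_h)
            + rng.normal(0.0, params.noise_sd, times.size)
        )
        traces.append(
            CellTrace(cell_id=f"cell_{condition}_{i:03d}", condition=condition, times_h=times, intensities=y)
        )
    return traces


def simulate_expression(
    kind: str,
    spec: SimulationSpec,
    gene: str = "gene",
    fold_amplitude: float = 9.0,
    clock_amplitude: float = 0.5,
    clock_phase_h: float = 6.0,
    noise_sd: float = 0.15,
    synchronized: bool = True,
    times_h: Sequence[float] | None = None,
) -> ExpressionCourse:
    """Simulate one relative-expression time course after light onset.

    * ``acute_inducible``  — sharp induction peaking at 3 h then decaying;
    * ``slow_inducible``   — slower rise peaking at 12 h;
    * ``clock_output``     — 24-h cosine (only when ``synchronized``);
    * ``flat``             — no induction.

    Multiplicative lognormal noise; the course is re-normalized so the value
    at time 0 is exactly 1.
    """
    if kind not in EXPRESSION_KINDS:
        raise ValueError(f"unknown expression kind {kind!r}")
    rng = np.random.default_rng(spec.seed)
    if times_h is None:
        times_h = np.arange(0.0, spec.duration_days * 24.0 + 1e-9, 3.0)
    t = np.asarray(times_h, dtype=float)
    if t[0] != 0.0:
        raise ValueError("expression timepoints must include 0")
    if kind == "acute_inducible":
        base = 1.0 + fold_amplitude * (t / 3.0) * np.exp(1.0 - t / 3.0)
    elif kind == "slow_inducible":
        base = 1.0 + fold_amplitude * (t / 12.0) ** 2 * np.exp(2.0 * (1.0 - t / 12.0))
    elif kind == "clock_output":
        if synchronized:
            base = 1.0 + clock_amplitude * np.cos(2 * np.pi * (t - clock_phase_h) / 24.0)
        else:
            base = np.ones_like(t)
    else:  # flat
        base = np.ones_like(t)
    values = base * np.exp(rng.normal(0.0, noise_sd, t.size)) if noise_sd > 0 else base
    return ExpressionCourse.from_raw(gene, t, values)


def simulate_crossover_bouts(
    n: int,
    seed: int,
    break_s: float = 60.0,
    slope_short: float = 0.5,
    slope_long: float = 2.5,
    min_s: float = 1.0,
) -> np.ndarray:
    """Immobile-bout lengths whose log-log survival curve is a broken line
    with its slope change exactly at ``break_s``.

    Survival is piecewise Pareto: S(L) = (L/min)^(-a) up to the break, then
    continues with the steeper exponent.  This is the constructed crossover
    used to validate the rest-threshold changepoint estimator; durations are
    rounded to whole seconds as 1-s binning would produce.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, n)
    s_break = (break_s / min_s) ** (-slope_short)
    short = u >= s_break
    out = np.empty(n)
    out[short] = min_s * u[short] ** (-1.0 / slope_short)
    out[~short] = break_s * (u[~short] / s_break) ** (-1.0 / slope_long)
    return np.maximum(np.round(out), 1.0)


def simulate_bout_pool(
    n: int,
    seed: int,
    pause_mean_s: float = 5.0,
    rest_median_s: float = 300.0,
    rest_sigma_log: float = 0.55,
    rest_weight: float = 0.1,
) -> np.ndarray:
    """Generic immobile-bout pool: a mixture of brief exponential pauses and
    lognormal consolidated rests (uncalibrated; see the methods note)."""
    rng = np.random.default_rng(seed)
    long = rng.random(n) < rest_weight
    out = np.empty(n)
    out[~long] = rng.exponential(pause_mean_s, (~long).sum())
    out[long] = rng.lognormal(np.log(rest_median_s), rest_sigma_log, long.sum())
    return np.maximum(np.round(out), 1.0)
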