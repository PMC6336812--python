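# Methods

This note documents the models and numerical choices behind `circalarva`:
what each analysis computes, what the synthetic-data generator emulates,
which parameters matter, and where the design was genuinely open.

## Time conventions

Behavioral time is seconds from recording start; circadian phase is
referenced to light onset (`ActivityTrack.t0_s` maps between the two). In
the simulated study design the recording starts at light onset, the light
pulse occupies the first 3 or 12 h, and all rhythm analysis is restricted to
the constant-darkness epoch after the pulse. Cell traces and expression
courses are sampled in hours after light onset.

## Bout analysis

A 1-s bin is active when its distance exceeds ε (default 0 mm: "no
detectable movement" is taken literally; ε is configurable because tracker
noise floors differ). Maximal same-state runs are bouts; the segmentation
is exactly a run-length encoding and is property-tested against an
independent linear-scan encoder.

Rest is an immobile bout of duration ≥ θ, default θ = 60 s. Derived
statistics over an analysis window (default days 1–3 after light onset):

- **Resting time per day** = Σ rest-bout seconds in window × 24 / window
  length. Rest bouts cut by the window edge are clipped into the sum.
- **Active–rest cycles** = number of rest bouts lying entirely inside the
  window (each rest bout terminates one cycle; the source studies leave
  this quantity undefined, so the convention is documented here).
- **Active periods** are maximal intervals containing no rest bout;
  immobile runs shorter than θ are absorbed. Periods whose extent is cut
  by a window edge (while the track continues beyond it) are censored:
  they are excluded from the per-period duration and distance means but
  their time still counts toward the window partition. A period that ends
  where the track itself ends is not considered censored — with real
  recordings this is a deliberate simplification, since the recording end
  censors too; it matters only for the first/last period of a track.
- Resting time is monotonically non-increasing in θ, and rest plus
  active-period time partitions the window exactly; both are tested.

Published summary tables of this experimental paradigm are internally
inconsistent (per-day cycle counts × mean active-period hours exceed any
possible window), so no single definition can reproduce every printed row;
the definitions above are self-consistent and recover the calibrated
generator parameters.

### Rest-threshold estimation

The pooled immobile-bout survival curve 1 − F(L) is fit on
log10–log10 axes by a continuous two-segment broken line, with the
breakpoint searched exhaustively over observed lengths (at least three
points per side). Points supported by fewer than 5 exceeding observations
are dropped first — empirical log-survival in the extreme tail is dominated
by sampling noise. The precondition is ≥ 50 distinct lengths spanning at
least a decade; otherwise the caller is directed to the default 60 s.

Validity: the broken line must reduce the squared residual by ≥ 20%
relative to the better of (a) a single straight line and (b) a cubic
polynomial with the same number of parameters. The cubic baseline is what
distinguishes a genuine slope break from smooth curvature: a single
exponential is strongly curved on log–log axes, so it beats a straight
line easily, but the cubic fits it as well as the broken line does
(measured improvement < 0 vs ≈ +0.7 for true broken-power-law pools).
On noiseless broken-power-law input the estimator returns the breakpoint
exactly; on sampled 5000-bout pools with a constructed crossover at 60 s it
recovers 55–63 s across seeds.

## Chi-square periodogram

Activity re-binned to 10-min totals is folded at every whole-bin candidate
period P in the scan band (default 16–32 h, i.e. 97 candidate periods at
10-min steps). With column means M_h, column occupancies n_h, grand mean
M̄ and N total bins,

    Q_P = N · Σ_h n_h (M_h − M̄)² / Σ_i (x_i − M̄)² ,

which reduces to the classical K·N·Σ(M_h − M̄)²/ΣSS form when all columns
hold K complete cycles, and is referenced to χ² with P_bins − 1 degrees of
freedom. The occupancy-weighted form handles series that are not whole
multiples of every candidate period without discarding data. Significance
uses a Bonferroni correction across the m scanned periods (threshold at the
1 − α/m quantile, α = 0.05); an animal is called rhythmic when the
periodogram *peak* exceeds its threshold and lies inside the 20–28 h
circadian band. Scan-edge peaks therefore never produce rhythmic calls.
Monte-Carlo under white noise confirms the family-wise false-positive rate
stays at or below α; a noiseless 24-h sinusoid peaks at exactly 24.0 h.
A normalized Lomb–Scargle periodogram over the same band is available as an
alternative statistic (no significance curve attached).

Degenerate series (zero variance — an animal that never moves) are an
error at the operation level; the behavior pipeline catches it and emits an
arrhythmic call with an undefined period, because a never-moving animal is
a valid, maximally-resting observation.

## Cosinor and circular statistics

The single-component cosinor y(t) = M + A·cos(2π(t − φ)/τ) is fit via the
linear parameterization (M, β, γ) with A = √(β² + γ²),
φ = (τ/2π)·atan2(γ, β) mod τ, by ordinary least squares. τ is fixed at
24 h for phase extraction and expression-rhythm calls (the analyses are
anchored to the 24-h cycle set by the light pulse); a free-period grid scan
is available explicitly. Rhythmicity is the zero-amplitude F-test,
F = ((RSS₀ − RSS)/2)/(RSS/(n − 3)). Acrophases are reported in [0, τ)
hours after light onset; values within 1e-9 of τ are wrapped to 0.

Traces are conditioned before fitting: deviation from a centered 24-h
moving average (edge windows shrink one-sided), then division by the
time-mean absolute intensity; a per-trace maximum-peak normalization is
available as a second mode. Per-trace (not per-experiment) normalization
was chosen where the published protocol is ambiguous. Detrending a damped
cosine slightly distorts its phase; with the preset damping range
(≤ 15%/day) the end-to-end phase error stays below 0.5 h (tested).

Cell phases are 2πφ/τ. A population of n phases is summarized by the
resultant z = Σ e^{iφ}/n: mean phase arg(z), resultant length R = |z|, and
the Rayleigh uniformity test using Zar's approximation
p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)), clipped to [0, 1] and
cross-checked in tests against an independent implementation. Cells
failing the zero-amplitude test at α = 0.05 are excluded from circular
summaries but always listed, never silently dropped. Circular histograms
default to 12 bins of 2 h.

## Synthetic-data generator

The generator encodes the study conditions; its defaults are not tuning
knobs.

**Behavior.** An alternating-renewal process: active-period durations are
lognormal (σ_log = 0.7) and rest-bout durations lognormal (σ_log = 0.55,
< 1% of mass below 60 s), both rounded to whole seconds. Within an active
period, movement seconds (gamma-distributed distances, shape 0.6) alternate
with short exponential pauses (mean 2 s, truncated below 60 s, one pause
per ~30 s of movement). Circadian control enters through the
rest-initiation hazard: after the light pulse ends, a drawn active-period
"exposure" E becomes a duration D = E/m(t) with
m(t) = 1 + d·cos(2π(t_h − 18)/24), solved quasi-statically (the hazard
peaks 12 h after the behavioral acrophase φ₀ = 6 h, placing peak activity
mid–subjective-day; φ₀ is a documented default, no phase values being
published). Before or without light there is no modulation — emulating
desynchronized cellular clocks producing no population rhythm.

Genotype presets are calibrated analytically: under the quasi-static model
the expected rest fraction is the circadian average of
ρ(u) = D_r·m(u)/(D_r·m(u) + D_a), and D_a is solved (Brent) so that the
12-h-pulse expectation hits the target resting time — 7.8 (WT), 20.5
(DKO), 20.6 (TKO) h/day, with mean rest bouts of 255/417/431 s chosen to
give ≈ 110/177/172 cycles per day. Modulation depths are
WT {0.9, 0.9}, DKO {0.03, 0.45}, TKO {0.03, 0.03} for {3-h, 12-h} pulses
and 0 in constant darkness, ordering the rhythmic ratios as the knockout
contrasts require. Mean per-moving-second distances (0.36/0.13/0.086 mm)
reproduce the order-of-magnitude collapse of per-period distance in the
knockouts.

**Cells.** I(t) = B(1 + st) + A(1 − δ)^{t/24}·cos(2π(t − φ)/τ) + ε with
defaults B = 10, A = 4, damping δ = 0.1/day, noise sd 0.3, slope s = 0;
φ is uniform on [0, τ) for dark-kept cultures or wrapped-normal
(mean 6 h, sd 1 h) for light-synchronized ones. The triple-knockout
culture is modeled as light-blind: uniform phases even after light.

**Expression.** Acute induction 1 + 9·(t/3)·e^{1−t/3} (peak exactly 3 h),
slow induction 1 + 9·(t/12)²·e^{2(1−t/12)} (peak 12 h), clock output
1 + 0.5·cos(2π(t − 6)/24) only when synchronized, flat controls;
multiplicative lognormal noise (σ = 0.15), then renormalization to 1 at
t = 0. Sampling every 3 h over one day.

**What the generator does not emulate:** developmental trends across days,
masking by light during the pulse itself, inter-animal parameter
heterogeneity beyond sampling noise, tracker artifacts (reflections,
dropped frames), non-stationary period drift, and cell division or
migration in imaging fields. Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes, not that real
tracking exports are free of artifacts the reader must still check.

## Problem sizes and determinism

Cohort analyses use n = 12 animals per genotype×condition over 4 simulated
days at 1-s resolution, 20 replicate 5000-bout pools for the changepoint,
50 seeds for cosinor/periodogram power, 100–200 replicates for Monte-Carlo
error rates, and 24 cells per culture condition — sizes at which every
stochastic check is stable across seeds while the whole suite runs in well
under a minute of simulation time. All randomness flows from
`numpy.random.default_rng` seeds; cohort members draw child seeds from a
`SeedSequence` spawn of the root seed, so each result table is a pure
function of (inputs, config, seed).

## Known limitations

- The periodogram's rhythmic/arrhythmic call depends on the global peak
  only; a series with a significant in-band peak masked by a larger
  out-of-band peak is called arrhythmic. This is the documented criterion,
  chosen to avoid counting scan-edge artifacts as rhythms.
- The broken-line changepoint assumes two power-law-like regimes; bout
  pools whose short-bout regime is strongly non-power-law can shift the
  breakpoint estimate even when a crossover exists.
- The zero-amplitude F-test assumes Gaussian residuals; on multiplicative
  lognormal expression noise its empirical type-I rate is close to, but
  can slightly exceed, the nominal 5% (measured ≈ 6.5% at n = 200).
- The quasi-static hazard approximation breaks down if active periods
  approach the circadian period in length; with the calibrated presets
  (minutes-long periods) the approximation error is far below the 10%
  recovery tolerance.
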