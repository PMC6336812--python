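import numpy as np
import pytest

from circalarva.bouts import bout_table, compute_rest_stats
from circalarva.model import LightSchedule
from circalarva.oscillation import extract_phase
from circalarva.simulate import (
    GenotypePreset,
    OscillatorParams,
    SimulationSpec,
    cell_params,
    preset,
    simulate_cells,
    simulate_cohort,
    simulate_expression,
    simulate_track,
)


class TestPresets:
    def test_resting_time_calibration_targets(self):
        assert preset("WT").expected_resting_time_h("pulse_12h") == pytest.approx(7.8, abs=0.01)
        assert preset("DKO").expected_resting_time_h("pulse_12h") == pytest.approx(20.5, abs=0.01)
        assert preset("TKO").expected_resting_time_h("pulse_12h") == pytest.approx(20.6, abs=0.01)

    def test_modulation_depth_ordering(self):
        wt, dko, tko = preset("WT"), preset("DKO"), preset("TKO")
        assert wt.mod_depth("pulse_3h") > dko.mod_depth("pulse_3h")
        assert dko.mod_depth("pulse_12h") > dko.mod_depth("pulse_3h")
        assert dko.mod_depth("pulse_12h") > tko.mod_depth("pulse_12h")
        assert all(p.mod_depth("DD") == 0.0 for p in (wt, dko, tko))

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            preset("Per2KO")


class TestSimulateTrack:
    def test_seed_determinism_and_sensitivity(self):
        spec = SimulationSpec(duration_days=0.5, schedule=LightSchedule.pulse(12.0), seed=5)
        a = simulate_track(preset("WT"), spec)
        b = simulate_track(preset("WT"), spec)
        assert np.array_equal(a.distances_mm, b.distances_mm)
        c = simulate_track(preset("WT"), SimulationSpec(duration_days=0.5, schedule=LightSchedule.pulse(12.0), seed=6))
        assert not np.array_equal(a.distances_mm, c.distances_mm)

    def test_unmodulated_rest_fraction_recovered(self):
        p = GenotypePreset.from_rest_fraction(0.85, mean_rest_bout_s=300.0)
        tr = simulate_track(p, SimulationSpec(duration_days=4.0, seed=21))
        st = compute_rest_stats(bout_table(tr), 60.0, (0.0, tr.duration_s))
        assert st.resting_time_h_per_day == pytest.approx(0.85 * 24, rel=0.10)

    def test_wt_pulsed_track_is_rhythmic_end_to_end(self):
        from circalarva.rhythm import chi_square_periodogram, classify_rhythmic, rebin_activity

        spec = SimulationSpec(duration_days=4.0, schedule=LightSchedule.pulse(12.0), seed=1)
        tr = simulate_track(preset("WT"), spec)
        post = tr.slice_seconds(12 * 3600.0, 12 * 3600.0 + 504 * 600.0)
        call = classify_rhythmic(chi_square_periodogram(rebin_activity(post, 600.0)))
        assert call.is_rhythmic
        assert 20 <= call.peak_period_h <= 28


class TestSimulateCells:
    def test_noiseless_phase_recovered_exactly(self):
        params = OscillatorParams(noise_sd=0.0, damping_per_day=0.0)
        spec = SimulationSpec(n=5, duration_days=3.0, seed=7)
        traces = simulate_cells(params, spec, "dark")
        rng = np.random.default_rng(7)  # regenerate the drawn phases
        for tr in traces:
            phi = rng.uniform(0.0, 24.0)
            rng.normal(0.0, 0.0, tr.times_h.size)  # keep the stream aligned
            ph = extract_phase(tr, 24.0)
            assert ph.acrophase_h == pytest.approx(phi % 24.0, abs=1e-6)

    def test_condition_maps_to_phase_mode(self):
        assert cell_params("dark").phase_mode == "uniform_random"
        assert cell_params("light_12h").phase_mode == "common"
        assert cell_params("light_12h", synchronizes=False).phase_mode == "uniform_random"

    def test_damped_noisy_pipeline_phase_error_below_half_hour(self):
        from circalarva.oscillation import detrend_trace, normalize_trace, fit_cosinor

        params = OscillatorParams(noise_sd=0.2, damping_per_day=0.15, trend_slope_per_h=0.002)
        traces = simulate_cells(params, SimulationSpec(n=12, duration_days=3.0, seed=8), "dark")
        rng = np.random.default_rng(8)
        for tr in traces:
            phi = rng.uniform(0.0, 24.0)
            rng.normal(0.0, params.noise_sd, tr.times_h.size)  # consume noise draws
            cond = normalize_trace(detrend_trace(tr, 24.0), "mean")
            fit = fit_cosinor(cond.times_h, cond.intensities, 24.0)
            err = abs(fit.acrophase_h - phi)
            assert min(err, 24 - err) < 0.5


class TestSimulateExpression:
    def test_acute_peaks_at_three_hours(self):
        c = simulate_expression("acute_inducible", SimulationSpec(duration_days=1.0, seed=0), noise_sd=0.0)
        assert c.times_h[np.argmax(c.values)] == 3.0

    def test_slow_peaks_at_twelve_hours(self):
        c = simulate_expression("slow_inducible", SimulationSpec(duration_days=1.0, seed=0), noise_sd=0.0)
        assert c.times_h[np.argmax(c.values)] == 12.0

    def test_unsynchronized_clock_output_is_flat(self):
        c = simulate_expression(
            "clock_output", SimulationSpec(duration_days=1.0, seed=0), synchronized=False, noise_sd=0.0
        )
        assert np.allclose(c.values, 1.0)

    def test_normalized_to_time_zero(self):
        c = simulate_expression("acute_inducible", SimulationSpec(duration_days=1.0, seed=3))
        assert c.values[0] == pytest.approx(1.0)

    def test_determinism_under_seed(self):
        spec = SimulationSpec(duration_days=1.0, seed=9)
        a = simulate_expression("clock_output", spec)
        b = simulate_expression("clock_output", spec)
        assert np.array_equal(a.values, b.values)


def test_expression_cosinor_power_and_type_one_error():
    """Cosinor at tau=24 detects simulated clock-output rhythms with power
    >= 0.9 and stays near the nominal 5% false-positive rate on flat courses
    (within the binomial envelope at n=200)."""
    from circalarva.oscillation import fit_cosinor

    hits = {"clock_output": 0, "flat": 0}
    for kind in hits:
        for rep in range(200):
            c = simulate_expression(kind, SimulationSpec(duration_days=1.0, seed=9000 + rep))
            hits[kind] += fit_cosinor(c.times_h, c.values, 24.0).p_zero_amplitude < 0.05
    assert hits["clock_output"] >= 180  # power >= 0.9
    assert hits["flat"] <= 200 * 0.05 + 2 * np.sqrt(200 * 0.05 * 0.95)


def test_cohort_child_seeds_differ():
    spec = SimulationSpec(n=3, duration_days=0.1, seed=4)
    tracks = simulate_cohort(preset("WT"), spec)
    assert len({tr.distances_mm.tobytes() for tr in tracks}) == 3
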