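import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circalarva.model import ArrhythmicCellError, CellTrace, CircalarvaError
from circalarva.oscillation import (
    circular_summary,
    detrend_trace,
    extract_phase,
    fit_cosinor,
    normalize_trace,
    rayleigh_p,
)


def _trace(y, dt_h=0.5, condition="dark"):
    y = np.asarray(y, dtype=float)
    return CellTrace("c", condition, np.arange(y.size) * dt_h, y)


class TestDetrend:
    def test_linear_ramp_interior_is_zero(self):
        t = np.arange(0, 72, 0.5)
        tr = _trace(5 + 0.3 * t)
        out = detrend_trace(tr, 24.0)
        interior = out.intensities[48:-48]
        assert np.max(np.abs(interior)) < 1e-9 * 0.3 * 24

    def test_constant_is_all_zero(self):
        out = detrend_trace(_trace(np.full(144, 7.0)), 24.0)
        assert np.allclose(out.intensities, 0.0)

    def test_cosine_plus_trend_recovers_cosine(self):
        t = np.arange(0, 96, 0.5)
        pure = 3 * np.cos(2 * np.pi * t / 24)
        out = detrend_trace(_trace(pure + 10 + 0.2 * t), 24.0)
        interior = slice(48, -48)
        r = np.corrcoef(out.intensities[interior], pure[interior])[0, 1]
        assert r > 0.99

    def test_short_trace_rejected(self):
        with pytest.raises(CircalarvaError):
            detrend_trace(_trace(np.ones(10)), 24.0)


class TestNormalize:
    def test_constant_mean_mode(self):
        out = normalize_trace(_trace(np.full(48, 5.0)), "mean")
        assert np.allclose(out.intensities, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10, 2, 100)
        a = normalize_trace(_trace(y), "mean")
        b = normalize_trace(_trace(10 * y), "mean")
        assert np.allclose(a.intensities, b.intensities)

    def test_mean_mode_postcondition(self):
        rng = np.random.default_rng(1)
        out = normalize_trace(_trace(rng.normal(4, 1, 200)), "mean")
        assert np.mean(np.abs(out.intensities)) == pytest.approx(1.0)

    def test_zero_divisor_rejected(self):
        with pytest.raises(CircalarvaError):
            normalize_trace(_trace(np.zeros(10)), "mean")


def _grid_search_cosinor(t, y, tau=24.0):
    """Independent oracle: dense grid over (M, A, phi), refined once."""
    best = (np.inf, None)
    m0, a0 = y.mean(), y.std() * np.sqrt(2)
    for M in np.linspace(m0 - 1, m0 + 1, 41):
        for A in np.linspace(max(a0 - 1, 0.01), a0 + 1, 41):
            for phi in np.linspace(0, tau, 97, endpoint=False):
                r = y - (M + A * np.cos(2 * np.pi * (t - phi) / tau))
                sse = r @ r
                if sse < best[0]:
                    best = (sse, (M, A, phi))
    return best[1]


class TestCosinor:
    def test_exact_recovery_noiseless(self):
        t = np.arange(0, 48.0)
        y = 10 + 3 * np.cos(2 * np.pi * (t - 6) / 24)
        f = fit_cosinor(t, y, 24.0)
        assert f.mesor == pytest.approx(10.0, abs=1e-9)
        assert f.amplitude == pytest.approx(3.0, abs=1e-9)
        assert f.acrophase_h == pytest.approx(6.0, abs=1e-9)
        assert f.p_zero_amplitude < 1e-12

    def test_constant_input_accepts_zero_amplitude(self):
        t = np.arange(0, 48.0)
        f = fit_cosinor(t, np.full(48, 2.0), 24.0)
        assert f.amplitude == pytest.approx(0.0, abs=1e-9)
        assert f.p_zero_amplitude > 0.99

    def test_noisy_recovery_and_grid_oracle_agreement(self):
        t = np.arange(0, 48.0)
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = 10 + 3 * np.cos(2 * np.pi * (t - 6) / 24) + rng.normal(0, 0.5, 48)
            f = fit_cosinor(t, y, 24.0)
            if abs(f.amplitude - 3) < 0.3 and abs(f.acrophase_h - 6) < 0.5:
                ok += 1
            M, A, phi = _grid_search_cosinor(t, y)
            assert abs(f.mesor - M) < 0.1
            assert abs(f.amplitude - A) < 0.1
            assert abs(f.acrophase_h - phi) < 0.3
        assert ok >= 9

    def test_degenerate_design_rejected(self):
        t = np.array([0.0, 24.0, 48.0, 72.0])  # all aliased mod 24
        from circalarva.model import DegenerateSeriesError

        with pytest.raises((DegenerateSeriesError, CircalarvaError)):
            fit_cosinor(t, np.ones(4), 24.0)


class TestExtractPhase:
    def test_acrophase_maps_to_circle_fraction(self):
        t = np.arange(0, 72, 0.5)
        y = np.cos(2 * np.pi * (t - 6) / 24)
        ph = extract_phase(_trace(y), 24.0)
        assert ph.phase_rad == pytest.approx(np.pi / 2, abs=1e-9)
        y0 = np.cos(2 * np.pi * t / 24)
        assert extract_phase(_trace(y0), 24.0).phase_rad == pytest.approx(0.0, abs=1e-9)

    def test_arrhythmic_cell_flagged_not_dropped(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ArrhythmicCellError, match="cell"):
            extract_phase(_trace(rng.normal(0, 1, 144)), 24.0)


class TestCircularSummary:
    def test_identical_phases_perfect_synchrony(self):
        cs = circular_summary(np.full(24, 1.3))
        assert cs.resultant_length == pytest.approx(1.0)
        assert cs.rayleigh_p < 1e-6

    def test_equally_spaced_phases_cancel(self):
        cs = circular_summary(np.linspace(0, 2 * np.pi, 24, endpoint=False))
        assert cs.resultant_length < 1e-12

    def test_matches_complex_sum_oracle(self):
        rng = np.random.default_rng(11)
        phases = rng.uniform(0, 2 * np.pi, 50)
        cs = circular_summary(phases)
        z = np.exp(1j * phases).mean()
        assert cs.resultant_length == pytest.approx(abs(z))
        assert cs.mean_phase_rad == pytest.approx(np.angle(z) % (2 * np.pi))
        n, R = 50, abs(z)
        p_direct = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - (n * R) ** 2)) - (1 + 2 * n))
        assert cs.rayleigh_p == pytest.approx(p_direct)

    def test_agrees_with_pingouin_rayleigh(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        phases = rng.vonmises(0, 1.0, 30) % (2 * np.pi)
        cs = circular_summary(phases)
        _, p_ref = pingouin.circ_rayleigh(phases)
        assert cs.rayleigh_p == pytest.approx(p_ref, rel=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 2 * np.pi))
    def test_rotation_equivariance(self, rot):
        rng = np.random.default_rng(13)
        phases = rng.uniform(0, 2 * np.pi, 20)
        a = circular_summary(phases)
        b = circular_summary((phases + rot) % (2 * np.pi))
        assert b.resultant_length == pytest.approx(a.resultant_length, abs=1e-9)
        diff = (b.mean_phase_rad - a.mean_phase_rad - rot) % (2 * np.pi)
        assert min(diff, 2 * np.pi - diff) < 1e-6

    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(14)
        cs = circular_summary(rng.uniform(0, 2 * np.pi, 37), n_bins=12)
        assert cs.histogram.sum() == 37

    def test_fewer_than_two_phases_rejected(self):
        with pytest.raises(CircalarvaError):
            circular_summary(np.array([1.0]))


def test_rayleigh_p_clipped_to_unit_interval():
    assert 0.0 <= rayleigh_p(5, 0.01) <= 1.0
    assert rayleigh_p(100, 0.9) < 1e-10
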