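import numpy as np
import pytest

from fnirsevents.aide_events import (AideParams, HRFParams, T_SENTINEL,
                                     build_regressor, canonical_hrf,
                                     detect_events, detect_events_naive,
                                     fast_t_grid, fit_glm, naive_t_grid)

WHITE = AideParams(signal_band=None)  # unit-test signals are not band-passed


class TestCanonicalHRF:
    def test_zero_at_origin(self):
        assert canonical_hrf()[0] == 0.0

    def test_peak_location(self):
        p = HRFParams()
        k = canonical_hrf(p, 10.0)
        peak_t = k.argmax() / 10.0
        assert peak_t == pytest.approx(p.peak_delay - p.peak_dispersion,
                                       abs=0.1)

    def test_single_sign_change(self):
        k = canonical_hrf()
        signs = np.sign(k[np.abs(k) > 1e-9])
        changes = np.count_nonzero(np.diff(signs))
        assert changes == 1


class TestBuildRegressor:
    def test_unit_boxcar_is_shifted_kernel(self):
        k = canonical_hrf()
        reg = build_regressor(10, 1, k, 100)
        raw = np.zeros(100)
        raw[10:10 + len(k)] = k
        expected = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(reg, expected, atol=1e-12)

    def test_shift_equivariance(self):
        k = canonical_hrf()
        a = build_regressor(20, 10, k, 300)
        b = build_regressor(120, 10, k, 300)
        np.testing.assert_allclose(np.roll(a, 100)[150:250], b[150:250],
                                   atol=1e-9)

    def test_matches_brute_force_convolution(self):
        k = canonical_hrf()
        n, onset, dur = 120, 30, 10
        brute = np.zeros(n)
        for t in range(n):
            brute[t] = sum(k[t - s] for s in range(onset, onset + dur)
                           if 0 <= t - s < len(k))
        brute = (brute - brute.mean()) / brute.std()
        np.testing.assert_allclose(build_regressor(onset, dur, k, n), brute,
                                   atol=1e-10)

    def test_boxcar_outside_recording_rejected(self):
        k = canonical_hrf()
        with pytest.raises(ValueError):
            build_regressor(95, 10, k, 100)


class TestFitGLM:
    def test_perfect_fit_reports_sentinel(self):
        reg = build_regressor(10, 5, canonical_hrf(), 100)
        beta, t = fit_glm(2.0 * reg + 1.0, reg)
        assert beta == pytest.approx(2.0)
        assert t == T_SENTINEL

    def test_orthogonal_signal_gives_zero_beta(self):
        reg = build_regressor(10, 5, canonical_hrf(), 200)
        y = np.zeros(200)
        beta, _t = fit_glm(y, reg)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            y = rng.normal(size=n)
            r = rng.normal(size=n)
            beta, t = fit_glm(y, r)
            x_mat = np.column_stack([r, np.ones(n)])
            coef = np.linalg.solve(x_mat.T @ x_mat, x_mat.T @ y)
            resid = y - x_mat @ coef
            sigma2 = resid @ resid / (n - 2)
            cov = sigma2 * np.linalg.inv(x_mat.T @ x_mat)
            assert beta == pytest.approx(coef[0], abs=1e-8)
            assert t == pytest.approx(coef[0] / np.sqrt(cov[0, 0]), abs=1e-8)

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(np.arange(10.0), np.ones(10))


class TestGridEquivalence:
    def test_incremental_grid_matches_naive_ols(self, rng):
        y = rng.normal(size=80)
        params = AideParams(max_duration=30, signal_band=None)
        fast = fast_t_grid(y, params)
        naive = naive_t_grid(y, params)
        both = np.isfinite(fast) & np.isfinite(naive)
        assert np.abs(fast[both] - naive[both]).max() < 1e-8
        assert (np.isfinite(fast) == np.isfinite(naive)).all()


class TestDetectEvents:
    def test_single_event_recovery(self):
        gen = np.random.default_rng(0)
        k = canonical_hrf()
        n = 600
        y = 3.0 * build_regressor(100, 30, k, n) + gen.normal(size=n)
        events = detect_events(y, WHITE)
        assert len(events) == 1
        assert abs(events[0].onset - 100) <= 2
        assert abs(events[0].duration - 30) <= 5

    def test_two_well_separated_events(self):
        gen = np.random.default_rng(3)
        k = canonical_hrf()
        n = 600
        y = (3.0 * build_regressor(100, 30, k, n)
             + 2.5 * build_regressor(300, 50, k, n) + gen.normal(size=n))
        events = detect_events(y, WHITE)
        assert len(events) == 2
        assert abs(events[0].onset - 100) <= 3
        assert abs(events[1].onset - 300) <= 3

    def test_pure_noise_yields_almost_no_events(self):
        total = sum(len(detect_events(
            np.random.default_rng(s).normal(size=600), WHITE))
            for s in range(10))
        assert total / 10 <= 1.0

    def test_amplitude_invariance(self):
        gen = np.random.default_rng(5)
        k = canonical_hrf()
        n = 600
        y = 3.0 * build_regressor(200, 40, k, n) + gen.normal(size=n)
        a = detect_events(y, WHITE)
        b = detect_events(7.5 * y, WHITE)
        assert [(e.onset, e.duration) for e in a] == \
            [(e.onset, e.duration) for e in b]
        for ea, eb in zip(a, b):
            assert ea.t_value == pytest.approx(eb.t_value, rel=1e-6)

    def test_time_shift_equivariance(self):
        gen = np.random.default_rng(8)
        k = canonical_hrf()
        noise = gen.normal(size=700)
        sig = 3.0 * build_regressor(150, 30, k, 700)
        y = sig + noise
        y_shift = np.roll(y, 40)
        a = detect_events(y, WHITE)
        b = detect_events(y_shift, WHITE)
        assert len(a) == len(b) == 1
        assert b[0].onset - a[0].onset == pytest.approx(40, abs=2)

    def test_deterministic(self):
        gen = np.random.default_rng(9)
        k = canonical_hrf()
        y = 3.0 * build_regressor(100, 25, k, 500) + gen.normal(size=500)
        a = detect_events(y, WHITE)
        b = detect_events(y.copy(), WHITE)
        assert a == b

    def test_durations_bounded(self):
        gen = np.random.default_rng(11)
        k = canonical_hrf()
        n = 700
        y = 4.0 * build_regressor(100, 300, k, n) + gen.normal(size=n)
        events = detect_events(y, WHITE)
        assert all(e.duration <= 230.0 for e in events)

    def test_matches_naive_greedy_without_calibration(self):
        gen = np.random.default_rng(4)
        k = canonical_hrf()
        n = 140
        y = 3.0 * build_regressor(40, 12, k, n) + gen.normal(size=n)
        params = AideParams(max_duration=25, noise_calibration=False,
                            refine_cycles=0, edge_exclusion_s=0)
        fast = detect_events(y, params)
        naive = detect_events_naive(y, AideParams(max_duration=25,
                                                  edge_exclusion_s=0))
        assert [(e.onset, e.duration) for e in fast] == \
            [(e.onset, e.duration) for e in naive]
        for ef, en in zip(fast, naive):
            assert ef.t_value == pytest.approx(en.t_value, abs=1e-8)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_events(np.zeros(10), WHITE)

    def test_constant_signal_yields_no_events(self):
        assert detect_events(np.ones(400), WHITE) == []
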