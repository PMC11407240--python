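import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sg

from fnirsevents.signal_quality import (QualityParams, assess_channels,
                                        compute_psp, compute_sci)

from conftest import make_recording


def _sine(freq, fs, dur, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


def _oracle_sci(a, b, fs, band=(0.5, 2.5)):
    """Independent direct band-pass + correlation implementation."""
    nyq = fs / 2
    hi = min(band[1], 0.98 * nyq)
    bcoef, acoef = sg.butter(3, [band[0] / nyq, hi / nyq], btype="band")
    fa = sg.filtfilt(bcoef, acoef, a - a.mean(), padlen=18)
    fb = sg.filtfilt(bcoef, acoef, b - b.mean(), padlen=18)
    return float(np.corrcoef(fa, fb)[0, 1])


class TestSCI:
    def test_identical_sinusoids_score_one(self):
        x = 1.0 + 0.1 * _sine(1.2, 10, 5)
        assert compute_sci(x, x, 10.0) == pytest.approx(1.0, abs=1e-6)

    def test_antiphase_sinusoids_score_minus_one(self):
        x = _sine(1.2, 10, 5)
        assert compute_sci(1 + 0.1 * x, 1 - 0.1 * x, 10.0) == \
            pytest.approx(-1.0, abs=1e-6)

    def test_matches_independent_oracle_on_noise(self, rng):
        a = _sine(1.1, 10, 5) + rng.normal(size=50)
        b = rng.normal(size=50)
        ours = compute_sci(a, b, 10.0)
        assert ours == pytest.approx(_oracle_sci(a, b, 10.0), abs=1e-9)
        assert abs(ours) < 0.6

    def test_constant_segment_is_missing(self):
        assert np.isnan(compute_sci(np.ones(50), _sine(1, 10, 5), 10.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50), offset=st.floats(-5, 5),
           seed=st.integers(0, 100))
    def test_symmetric_and_affine_invariant(self, scale, offset, seed):
        gen = np.random.default_rng(seed)
        a = _sine(1.0, 10, 5) + 0.3 * gen.normal(size=50)
        b = _sine(1.0, 10, 5, 0.4) + 0.3 * gen.normal(size=50)
        base = compute_sci(a, b, 10.0)
        assert compute_sci(b, a, 10.0) == pytest.approx(base, abs=1e-9)
        assert compute_sci(scale * a + offset, b, 10.0) == \
            pytest.approx(base, abs=1e-7)


class TestPSP:
    def test_shared_cardiac_sinusoid_passes_threshold(self):
        x = _sine(1.1, 10, 5)
        psp = compute_psp(1 + 0.1 * x, 2 + 0.2 * x, 10.0)
        assert psp >= 0.1
        assert psp == pytest.approx(1.0, abs=0.5)  # normalised near unity

    def test_independent_noise_rarely_passes(self):
        gen = np.random.default_rng(7)
        below = sum(compute_psp(gen.normal(size=50), gen.normal(size=50),
                                10.0) < 0.1 for _ in range(100))
        assert below >= 90

    def test_zero_variance_is_missing(self):
        assert np.isnan(compute_psp(np.full(50, 2.0), _sine(1, 10, 5), 10.0))


class TestAssessChannels:
    def test_shared_cardiac_channel_included(self, montage2):
        rec = make_recording(montage2, n_samples=300, cardiac_amp=0.05)
        report = assess_channels(rec)
        assert report.included.all()
        assert report.fail_fraction[0] == 0.0
        assert report.participant_included

    def test_pure_noise_channel_excluded(self, montage2):
        rec = make_recording(montage2, n_samples=300, cardiac_amp=0.05)
        gen = np.random.default_rng(3)
        rec.intensities[1, 0] = 1 + 0.01 * gen.normal(size=300)
        rec.intensities[1, 1] = 1 + 0.01 * gen.normal(size=300)
        report = assess_channels(rec)
        assert report.included[0] and not report.included[1]
        assert report.participant_included

    def test_all_noise_participant_excluded(self, montage2):
        rec = make_recording(montage2, n_samples=300, cardiac_amp=0.05)
        gen = np.random.default_rng(4)
        rec.intensities = 1 + 0.01 * gen.normal(size=rec.intensities.shape)
        rec.intensities = np.abs(rec.intensities) + 0.1
        report = assess_channels(rec)
        assert not report.included.any()
        assert not report.participant_included

    def test_window_count_ignores_trailing_partial(self, montage2):
        rec = make_recording(montage2, n_samples=140)  # 28 s at 5 Hz
        report = assess_channels(rec, QualityParams(window_s=5.0))
        assert report.sci.shape[1] == 5

    def test_batch_matches_scalar_metrics(self, montage2):
        rec = make_recording(montage2, n_samples=150, cardiac_amp=0.03)
        params = QualityParams()
        report = assess_channels(rec, params)
        win = int(5 * rec.sampling_rate)
        for c in range(2):
            for k in range(report.sci.shape[1]):
                s = slice(k * win, (k + 1) * win)
                sci = compute_sci(rec.intensities[c, 0, s],
                                  rec.intensities[c, 1, s],
                                  rec.sampling_rate)
                psp = compute_psp(rec.intensities[c, 0, s],
                                  rec.intensities[c, 1, s],
                                  rec.sampling_rate)
                assert report.sci[c, k] == pytest.approx(sci, abs=1e-8)
                assert report.psp[c, k] == pytest.approx(psp, abs=1e-8)

    def test_manual_exclusion_applies(self, montage2):
        rec = make_recording(montage2, n_samples=300, cardiac_amp=0.05)
        report = assess_channels(rec, QualityParams(manual_exclusions=(0,)))
        assert not report.included[0] and report.included[1]

    def test_exclusion_monotone_in_thresholds(self, montage2):
        rec = make_recording(montage2, n_samples=300, cardiac_amp=0.008)
        strict = assess_channels(rec, QualityParams(sci_threshold=0.9,
                                                    psp_threshold=0.5))
        lax = assess_channels(rec, QualityParams(sci_threshold=0.1,
                                                 psp_threshold=0.01))
        # lowering thresholds can only shrink the excluded set
        assert (~strict.included | lax.included).all() or \
            lax.included.sum() >= strict.included.sum()
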