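"""Windowed channel-quality metrics and exclusion rules.

The two wavelengths of a well-coupled channel share the cardiac pulsation,
so their cardiac-band-filtered segments are strongly correlated (SCI) and
their normalised cross-correlation has a strong spectral peak (PSP).
Quality is judged in non-overlapping windows; a window fails when *both*
metrics fall below threshold, and a channel is excluded when more than a
set fraction of its windows fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data_io import RawRecording


@dataclass
class QualityParams:
    window_s: float = 5.0
    sci_threshold: float = 0.6
    psp_threshold: float = 0.1
    bad_window_fraction: float = 0.5
    cardiac_band: tuple[float, float] = (0.5, 2.5)
    manual_exclusions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValueError("window_s must be positive")
        if not -1 <= self.sci_threshold <= 1:
            raise ValueError("sci_threshold must lie in [-1, 1]")
        if self.psp_threshold < 0:
            raise ValueError("psp_threshold must be >= 0")
        if not 0 < self.bad_window_fraction < 1:
            raise ValueError("bad_window_fraction must lie in (0, 1)")


@dataclass
class QualityReport:
    sci: np.ndarray            # (channel, window), NaN where undefined
    psp: np.ndarray            # (channel, window)
    fail_fraction: np.ndarray  # (channel,)
    included: np.ndarray       # (channel,) bool
    participant_included: bool
    manual_exclusions: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        def _clean(a):
            return [None if not np.isfinite(v) else float(v) for v in a]
        return {
            "sci": [_clean(row) for row in self.sci],
            "psp": [_clean(row) for row in self.psp],
            "fail_fraction": [float(v) for v in self.fail_fraction],
            "included": [bool(v) for v in self.included],
            "participant_included": bool(self.participant_included),
            "manual_exclusions": list(self.manual_exclusions),
        }


def _cardiac_filter(x: np.ndarray, fs: float,
                    band: tuple[float, float]) -> np.ndarray:
    """3rd-order zero-phase Butterworth band-pass after mean removal.

    The upper edge is clamped just below Nyquist (it equals Nyquist at the
    common 5 Hz sampling rate)."""
    nyq = fs / 2.0
    lo = band[0]
    hi = min(band[1], 0.98 * nyq)
    if not 0 < lo < hi:
        raise ValueError(f"cardiac band {band} invalid at fs={fs}")
    sos = signal.butter(3, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = x - x.mean()
    padlen = min(len(x) - 1, 3 * 6)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def compute_sci(window_w1: np.ndarray, window_w2: np.ndarray, sampling_rate: float,
                cardiac_band: tuple[float, float] = (0.5, 2.5)) -> float:
    """Scalp coupling index: Pearson correlation of the cardiac-band-filtered,
    amplitude-normalised wavelength pair. NaN for degenerate windows."""
    w1 = np.asarray(window_w1, float)
    w2 = np.asarray(window_w2, float)
    if len(w1) != len(w2) or len(w1) < 4:
        raise ValueError("segments must have equal length >= 4 samples")
    if np.std(w1) == 0 or np.std(w2) == 0:
        return float("nan")
    a = _cardiac_filter(w1, sampling_rate, cardiac_band)
    b = _cardiac_filter(w2, sampling_rate, cardiac_band)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))


def compute_psp(window_w1: np.ndarray, window_w2: np.ndarray, sampling_rate: float,
                cardiac_band: tuple[float, float] = (0.5, 2.5)) -> float:
    """Peak spectral power of the normalised cross-correlation.

    The cross-correlation is normalised per lag by the un-overlapped sample
    count and the segment standard deviations (so a perfectly shared
    sinusoid gives a unit-amplitude cosine in lag), restricted to lags
    within +-n/2, and its Hamming periodogram peak is scaled so that the
    shared-sinusoid case scores approximately 1.
    """
    w1 = np.asarray(window_w1, float)
    w2 = np.asarray(window_w2, float)
    if len(w1) != len(w2) or len(w1) < 4:
        raise ValueError("segments must have equal length >= 4 samples")
    if np.std(w1) == 0 or np.std(w2) == 0:
        return float("nan")
    a = _cardiac_filter(w1, sampling_rate, cardiac_band)
    b = _cardiac_filter(w2, sampling_rate, cardiac_band)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    n = len(a)
    c = signal.correlate(a - a.mean(), b - b.mean(), mode="full")
    lags = np.arange(-(n - 1), n)
    c = c / ((n - np.abs(lags)) * sa * sb)
    keep = np.abs(lags) <= n // 2
    _f, pxx = signal.periodogram(c[keep], fs=sampling_rate,
                                 window="hamming", scaling="spectrum")
    return float(2.0 * pxx.max())


def _batch_quality(rec: RawRecording, params: QualityParams, win: int,
                   n_win: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised SCI/PSP over all channels and windows.

    Step-for-step identical to the scalar :func:`compute_sci` /
    :func:`compute_psp` (asserted by tests); the cross-correlations go
    through zero-padded FFTs instead of per-window direct correlation.
    """
    fs = rec.sampling_rate
    nyq = fs / 2.0
    lo = params.cardiac_band[0]
    hi = min(params.cardiac_band[1], 0.98 * nyq)
    if not 0 < lo < hi:
        raise ValueError(f"cardiac band {params.cardiac_band} invalid at fs={fs}")
    sos = signal.butter(3, [lo / nyq, hi / nyq], btype="band", output="sos")
    n_ch = rec.n_channels
    w = rec.intensities[:, :, :n_win * win].reshape(n_ch, 2, n_win, win)
    degenerate = (w.std(axis=-1) == 0).any(axis=1)          # (ch, win)
    x = w - w.mean(axis=-1, keepdims=True)
    padlen = min(win - 1, 3 * 6)
    f = signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)
    fc = f - f.mean(axis=-1, keepdims=True)
    sd = f.std(axis=-1)                                      # (ch, 2, win)
    degenerate |= (sd == 0).any(axis=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    a = fc[:, 0]
    b = fc[:, 1]
    sci = (a * b).mean(axis=-1) / (sd_safe[:, 0] * sd_safe[:, 1])
    # full linear cross-correlation via zero-padded FFT
    nfft = 2 * win
    fa = np.fft.rfft(a, nfft, axis=-1)
    fb = np.fft.rfft(b, nfft, axis=-1)
    cc = np.fft.irfft(fa * np.conj(fb), nfft, axis=-1)
    full = np.concatenate([cc[..., -(win - 1):], cc[..., :win]], axis=-1)
    lags = np.arange(-(win - 1), win)
    full = full / ((win - np.abs(lags)) * sd_safe[:, 0, :, None]
                   * sd_safe[:, 1, :, None])
    keep = np.abs(lags) <= win // 2
    _freqs, pxx = signal.periodogram(full[..., keep], fs=fs,
                                     window="hamming", scaling="spectrum",
                                     axis=-1)
    psp = 2.0 * pxx.max(axis=-1)
    sci[degenerate] = np.nan
    psp[degenerate] = np.nan
    return sci, psp


def assess_channels(rec: RawRecording, params: QualityParams | None = None
                    ) -> QualityReport:
    """Apply the windowed SCI/PSP rules to every channel of a recording.

    A window fails iff SCI < threshold AND PSP < threshold (undefined
    metrics count as failing); a channel is excluded iff its failing
    fraction exceeds ``bad_window_fraction``; the participant is excluded
    iff every channel is excluded. Trailing partial windows are ignored.
    """
    params = params or QualityParams()
    win = int(round(params.window_s * rec.sampling_rate))
    n_win = rec.n_samples // win
    if n_win < 1:
        raise ValueError("recording shorter than one quality window")
    n_ch = rec.n_channels
    sci, psp = _batch_quality(rec, params, win, n_win)
    sci_fail = np.where(np.isnan(sci), True, sci < params.sci_threshold)
    psp_fail = np.where(np.isnan(psp), True, psp < params.psp_threshold)
    fail = sci_fail & psp_fail
    frac = fail.mean(axis=1)
    included = frac <= params.bad_window_fraction
    for c in params.manual_exclusions:
        included[c] = False
    return QualityReport(sci=sci, psp=psp, fail_fraction=frac,
                         included=included,
                         participant_included=bool(included.any()),
                         manual_exclusions=tuple(params.manual_exclusions))
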