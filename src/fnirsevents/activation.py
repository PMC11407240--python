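"""CBSI activation signals and 1 Hz down-sampling.

Correlation-based signal improvement (CBSI) assumes that the evoked
response raises HbO2 and lowers HbR proportionally while motion and
systemic physiology move both in the same direction; enforcing perfect
anti-correlation between the corrected pair cancels the common-mode part:

    alpha = sigma(HbO) / sigma(HbR)
    x     = (HbO - alpha * HbR) / 2        # activation signal
    HbR'  = -x / alpha                     # corrected HbR

The activation signal is block-averaged to 1 Hz before event detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import HaemoSeries


@dataclass
class ActivationSignal:
    x: np.ndarray              # (channel, time)
    sampling_rate: float
    alpha: np.ndarray          # (channel,)


def cbsi(hbo: np.ndarray, hbr: np.ndarray
         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (activation, corrected_hbr, alpha) for one channel.

    By construction corr(activation, corrected_hbr) = -1 exactly, and the
    output is invariant under joint rescaling of both inputs.
    """
    hbo = np.asarray(hbo, float)
    hbr = np.asarray(hbr, float)
    if hbo.shape != hbr.shape or hbo.ndim != 1 or len(hbo) < 2:
        raise ValueError("hbo and hbr must be equal-length 1-d series, n >= 2")
    s_hbr = hbr.std()
    if s_hbr == 0:
        raise ValueError("zero-variance HbR: channel must be flagged")
    alpha = float(hbo.std() / s_hbr)
    activation = (hbo - alpha * hbr) / 2.0
    corrected_hbr = -activation / alpha
    return activation, corrected_hbr, alpha


def apply_cbsi(haemo: HaemoSeries) -> ActivationSignal:
    """CBSI per channel over the full preprocessed recording."""
    n_ch = haemo.hbo.shape[0]
    x = np.empty_like(haemo.hbo)
    alpha = np.empty(n_ch)
    for c in range(n_ch):
        x[c], _, alpha[c] = cbsi(haemo.hbo[c], haemo.hbr[c])
    return ActivationSignal(x, haemo.sampling_rate, alpha)


def downsample_1hz(x: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Non-overlapping 1 s block means; output length floor(duration).

    Block averaging doubles as a box anti-alias filter and preserves the
    signal mean over whole seconds exactly (integer sampling rates).
    """
    if sampling_rate < 1:
        raise ValueError("sampling_rate must be >= 1 Hz")
    x = np.asarray(x, float)
    n = x.shape[-1]
    n_out = int(np.floor(n / sampling_rate))
    if n_out < 1:
        raise ValueError("series shorter than one second")
    edges = np.floor(np.arange(n_out + 1) * sampling_rate).astype(int)
    trimmed = x[..., :edges[-1]]
    sums = np.add.reduceat(trimmed, edges[:-1], axis=-1)
    counts = np.diff(edges)
    return sums / counts


def activation_at_1hz(haemo: HaemoSeries) -> ActivationSignal:
    """CBSI followed by down-sampling to 1 Hz (the detector's input rate)."""
    act = apply_cbsi(haemo)
    x1 = downsample_1hz(act.x, act.sampling_rate)
    return ActivationSignal(x1, 1.0, act.alpha)
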