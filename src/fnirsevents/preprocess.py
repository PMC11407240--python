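"""Haemodynamic preprocessing chain.

intensity -> optical density -> wavelet motion correction -> zero-phase
band-pass -> modified Beer-Lambert law (MBLL) concentrations.

Conventions: natural-log optical density relative to the per-series mean
intensity; concentrations in uM; source-detector distance in cm; the
shipped molar extinction coefficients are the Prahl compilation values for
760/850 nm in cm^-1/M. The absolute concentration scale cancels out of
every downstream t-statistic, and the synthetic forward model uses the
same table, so round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .data_io import Montage, RawRecording, ValidationError

# molar extinction coefficients, cm^-1 / (mol/L)  (Prahl compilation)
EXTINCTION_CM_PER_M: dict[float, dict[str, float]] = {
    760.0: {"hbo": 586.0, "hbr": 1548.52},
    850.0: {"hbo": 1058.0, "hbr": 691.32},
}


@dataclass
class ODSeries:
    """Optical density change, indexed (channel, wavelength, time)."""
    od: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, float)
        if self.od.ndim != 3 or self.od.shape[1] != 2:
            raise ValidationError("od must be (channel, 2, time)")
        if not np.isfinite(self.od).all():
            raise ValidationError("non-finite optical density")


@dataclass
class HaemoSeries:
    """Concentration changes in uM, indexed (channel, time)."""
    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, float)
        self.hbr = np.asarray(self.hbr, float)
        if self.hbo.shape != self.hbr.shape:
            raise ValidationError("hbo and hbr must have the same shape")


@dataclass
class PreprocessParams:
    wavelet_iqr: float = 1.5
    band: tuple[float, float] = (0.01, 0.3)
    filter_order: int = 5
    dpf: tuple[float, float] = (6.0, 6.0)
    extinction: dict[float, dict[str, float]] = field(
        default_factory=lambda: EXTINCTION_CM_PER_M)


def intensity_to_od(rec: RawRecording) -> ODSeries:
    """OD(c, w, t) = -ln( I(c, w, t) / mean_t I(c, w, .) ).

    Invariant to rescaling the detector gain of any channel/wavelength.
    """
    i = rec.intensities
    bad = np.argwhere(~(i > 0))
    if bad.size:
        c, w, t = bad[0]
        raise ValidationError(
            f"non-positive intensity at channel {c}, wavelength index {w}, "
            f"sample {t}")
    od = -np.log(i / i.mean(axis=2, keepdims=True))
    return ODSeries(od, rec.sampling_rate)


def _wavelet_correct_1d(x: np.ndarray, iqr_factor: float,
                        sampling_rate: float) -> np.ndarray:
    n = len(x)
    if n < 4:
        raise ValueError("series too short for one decomposition level")
    wavelet = "db2"
    # cap the depth so every thresholded detail band lies above the
    # haemodynamic band (~<0.1 Hz): evoked responses are sparse and
    # smooth, so at deeper levels their coefficients are exactly the
    # outliers the IQR rule would delete
    protect_hz = 0.125
    depth_cap = max(1, int(np.floor(np.log2(sampling_rate / (2 * protect_hz)))))
    level = min(pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len),
                depth_cap)
    if level < 1:
        raise ValueError("series too short for one decomposition level")
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=level)
    if np.isinf(iqr_factor):
        return x.copy()
    for j in range(1, len(coeffs)):  # detail levels only
        c = coeffs[j]
        med = np.median(c)
        q1, q3 = np.percentile(c, [25, 75])
        iqr = q3 - q1
        outlier = np.abs(c - med) > iqr_factor * iqr
        c[outlier] = 0.0
    out = pywt.waverec(coeffs, wavelet, mode="periodization")
    return out[:n]


def wavelet_motion_correct(od: ODSeries, iqr_factor: float = 1.5) -> ODSeries:
    """Suppress motion artifacts by zeroing outlying wavelet detail
    coefficients (deviation from the level median beyond
    ``iqr_factor`` x inter-quartile range), channel by channel."""
    out = np.empty_like(od.od)
    n_ch, n_wl, _ = od.od.shape
    for c in range(n_ch):
        for w in range(n_wl):
            out[c, w] = _wavelet_correct_1d(od.od[c, w], iqr_factor,
                                            od.sampling_rate)
    return ODSeries(out, od.sampling_rate)


def bandpass(od: ODSeries, band: tuple[float, float] = (0.01, 0.3),
             order: int = 5) -> ODSeries:
    """Zero-phase (forward-backward) Butterworth band-pass per series."""
    nyq = od.sampling_rate / 2.0
    if not 0 < band[0] < band[1]:
        raise ValueError(f"invalid band {band}")
    if band[1] >= nyq:
        raise ValueError(f"band edge {band[1]} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [band[0] / nyq, band[1] / nyq],
                        btype="band", output="sos")
    out = signal.sosfiltfilt(sos, od.od, axis=-1)
    return ODSeries(out, od.sampling_rate)


def _extinction_matrix(wavelengths: tuple[float, float],
                       table: dict[float, dict[str, float]]) -> np.ndarray:
    rows = []
    for wl in wavelengths:
        if wl not in table:
            raise ValueError(f"no extinction coefficients for {wl} nm")
        rows.append([table[wl]["hbo"], table[wl]["hbr"]])
    e = np.asarray(rows, float)
    if abs(np.linalg.det(e)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    return e


def od_to_concentration(od: ODSeries, montage: Montage,
                        params: PreprocessParams | None = None) -> HaemoSeries:
    """MBLL inversion: per channel solve E . [dHbO; dHbR] = dOD / (d . DPF).

    ``d`` is the source-detector separation in cm; the result is in uM.
    """
    params = params or PreprocessParams()
    e = _extinction_matrix(montage.wavelengths, params.extinction)
    e_inv = np.linalg.inv(e)
    n_ch = od.od.shape[0]
    if n_ch != montage.n_channels:
        raise ValidationError("channel count mismatch between OD and montage")
    hbo = np.empty((n_ch, od.od.shape[2]))
    hbr = np.empty_like(hbo)
    for c, (_s, _d, sep_mm) in enumerate(montage.channels):
        d_cm = sep_mm / 10.0
        pathlength = d_cm * np.asarray(params.dpf)  # per wavelength
        scaled = od.od[c] / pathlength[:, None]     # (2, time)
        conc_m = e_inv @ scaled                     # mol/L
        hbo[c] = conc_m[0] * 1e6
        hbr[c] = conc_m[1] * 1e6
    return HaemoSeries(hbo, hbr, od.sampling_rate)


def concentration_to_od(hbo: np.ndarray, hbr: np.ndarray, montage: Montage,
                        params: PreprocessParams | None = None,
                        sampling_rate: float = 1.0) -> ODSeries:
    """Forward MBLL (the exact inverse of :func:`od_to_concentration`);
    used by the synthetic generator and round-trip tests."""
    params = params or PreprocessParams()
    e = _extinction_matrix(montage.wavelengths, params.extinction)
    hbo = np.asarray(hbo, float)
    hbr = np.asarray(hbr, float)
    n_ch, n_t = hbo.shape
    od = np.empty((n_ch, 2, n_t))
    for c, (_s, _d, sep_mm) in enumerate(montage.channels):
        d_cm = sep_mm / 10.0
        pathlength = d_cm * np.asarray(params.dpf)
        conc_m = np.vstack([hbo[c], hbr[c]]) * 1e-6
        od[c] = (e @ conc_m) * pathlength[:, None]
    return ODSeries(od, sampling_rate)


def preprocess_recording(rec: RawRecording,
                         params: PreprocessParams | None = None) -> HaemoSeries:
    """Full chain: OD -> wavelet correction -> band-pass -> MBLL."""
    params = params or PreprocessParams()
    od = intensity_to_od(rec)
    od = wavelet_motion_correct(od, params.wavelet_iqr)
    od = bandpass(od, params.band, params.filter_order)
    return od_to_concentration(od, rec.montage, params)
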