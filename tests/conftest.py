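import numpy as np
import pytest

from fnirsevents.data_io import (ConditionTimeline, Interval, Montage,
                                 RawRecording, default_montage)


@pytest.fixture
def montage20() -> Montage:
    return default_montage()


@pytest.fixture
def montage2() -> Montage:
    return Montage(sources={"S1": (0.0, 0.0), "S2": (60.0, 0.0)},
                   detectors={"D1": (0.0, 30.0), "D2": (60.0, 30.0)},
                   channels=[("S1", "D1", 30.0), ("S2", "D2", 30.0)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_recording(montage, n_samples=100, fs=5.0, seed=0,
                   cardiac_hz=1.1, cardiac_amp=0.02):
    """Small positive-intensity recording with a shared cardiac tone on
    both wavelengths of every channel."""
    gen = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    n_ch = montage.n_channels
    intens = np.empty((n_ch, 2, n_samples))
    for c in range(n_ch):
        pulse = cardiac_amp * np.sin(2 * np.pi * cardiac_hz * t
                                     + gen.uniform(0, 2 * np.pi))
        for w in range(2):
            base = gen.uniform(0.5, 2.0)
            intens[c, w] = base * (1 + pulse
                                   + 1e-3 * gen.normal(size=n_samples))
    return RawRecording(intens, fs, montage)


@pytest.fixture
def recording2(montage2) -> RawRecording:
    return make_recording(montage2)


@pytest.fixture
def timeline12() -> ConditionTimeline:
    """Both conditions, both phases: 6 dynamic cells + 6 static trials."""
    intervals = []
    t = 60.0
    for cond in ("fragranced", "unfragranced"):
        for task, dur in (("wash", 200.0), ("dry_hang", 300.0),
                          ("fold", 200.0)):
            intervals.append(Interval(f"{cond}_{task}", "dynamic", cond,
                                      task, t, t + dur))
            t += dur + 20.0
    for cond in ("fragranced", "unfragranced"):
        for task in ("liquid", "wet", "dry"):
            intervals.append(Interval(f"{cond}_{task}", "static", cond,
                                      task, t, t + 40.0))
            t += 60.0
    return ConditionTimeline(intervals)
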