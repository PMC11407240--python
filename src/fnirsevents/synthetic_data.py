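"""Seeded, ground-truthed synthetic fNIRS study datasets.

The generator inverts the analysis chain: evoked concentration responses
(HRF-convolved boxcars, dHbR = -dHbO/3) plus physiological oscillations
are laid down in concentration space, mapped through the forward
Beer-Lambert model to optical density, where drift, white noise and
spike/shift motion artifacts are added, and finally exponentiated to raw
two-wavelength intensities. Poorly coupled channels are emitted as pure
noise with no shared cardiac component so that the quality screen has
something real to find. Every random draw comes from one seeded
generator, so a spec + seed pins the full dataset bit-exactly.

All default magnitudes are invented study conditions (documented in
docs/methods.md); nothing downstream depends on the absolute scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .aide_events import HRFParams, canonical_hrf
from .data_io import (CONDITIONS, ConditionTimeline, Interval, Montage,
                      RawRecording, STATIC_TASKS, default_montage,
                      validate_questionnaire)
from .preprocess import PreprocessParams, concentration_to_od


@dataclass
class SyntheticSpec:
    n_participants: int = 16
    n_channels: int = 20
    sampling_rate: float = 5.0
    # condition duration ranges, s
    wash_duration: tuple[float, float] = (180.0, 360.0)
    dry_hang_duration: tuple[float, float] = (300.0, 600.0)
    fold_duration: tuple[float, float] = (180.0, 360.0)
    static_duration: tuple[float, float] = (30.0, 60.0)
    gap_duration: tuple[float, float] = (10.0, 30.0)
    lead_in_s: float = 150.0
    tail_s: float = 150.0
    # events
    dynamic_event_rate: float = 1.5   # expected events per channel-cell
    static_event_rate: float = 0.8
    event_duration: tuple[float, float] = (15.0, 60.0)
    event_min_gap_s: float = 15.0
    event_amplitude_mean: float = 1.2  # uM dHbO plateau
    event_amplitude_sd: float = 0.25
    hbr_ratio: float = -1.0 / 3.0
    # physiological oscillations (uM amplitude in HbO; HbR gets hbr_noise_ratio x)
    cardiac_freq: tuple[float, float] = (0.9, 1.3)
    cardiac_amp: float = 0.2
    resp_freq: tuple[float, float] = (0.2, 0.3)
    resp_amp: float = 0.05
    mayer_freq_mean: float = 0.1
    mayer_freq_sd: float = 0.01
    mayer_amp: float = 0.05
    hbr_noise_ratio: float = 1.0 / 3.0
    # optical-density-level noise
    od_white_sd: float = 5e-4
    od_drift_sd: float = 0.002         # total drift over the recording
    spike_rate_per_min: float = 0.2
    spike_amplitude: tuple[float, float] = (0.02, 0.1)
    shift_rate_per_min: float = 0.05
    shift_amplitude: float = 0.01
    fraction_bad: float = 0.1
    bad_channel_white_sd: float = 5e-3
    # planted condition effect: multiplier on event rate and amplitude in
    # the named condition, restricted to effect_channels
    effect_multiplier: float = 1.0
    effect_condition: str = "unfragranced"
    effect_channels: tuple[int, ...] = (14,)
    # questionnaire model
    questionnaire_noise_sd: float = 1.0
    intensity_linkage: float = 5.0     # scale points per unit latent amplitude
    # explicit event placement (channel, onset s, duration s, amplitude uM);
    # when given, Poisson drawing is skipped for every participant
    fixed_events: tuple[tuple[int, float, float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_channels < 1:
            raise ValueError("participant and channel counts must be >= 1")
        if self.effect_multiplier < 0:
            raise ValueError("rates and multipliers must be >= 0")
        if self.effect_condition not in CONDITIONS:
            raise ValueError(f"unknown effect condition {self.effect_condition!r}")


QUESTIONNAIRE_MEANS = {
    "fragranced": {"liking": 6.5, "intensity": 6.0, "invigorating": 5.5,
                   "relaxing": 5.5, "just_about_right": 3.0},
    "unfragranced": {"liking": 4.5, "intensity": 1.5, "invigorating": 3.0,
                     "relaxing": 4.0, "just_about_right": 2.0},
}


@dataclass
class TrueEvent:
    onset: float
    duration: float
    amplitude: float
    phase: str
    task: str
    condition: str


@dataclass
class GroundTruth:
    events: dict[str, dict[int, list[TrueEvent]]]
    bad_channels: dict[str, list[int]]
    amplitude_scale: dict[str, float]   # per-participant latent multiplier


@dataclass
class SyntheticStudy:
    recordings: dict[str, RawRecording]
    timelines: dict[str, ConditionTimeline]
    questionnaire: pd.DataFrame
    ground_truth: GroundTruth
    spec: SyntheticSpec


def _montage_subset(n_channels: int) -> Montage:
    m = default_montage()
    if n_channels == m.n_channels:
        return m
    if n_channels > m.n_channels:
        raise ValueError("default montage supports at most 20 channels")
    channels = m.channels[:n_channels]
    return Montage(m.sources, m.detectors, channels, m.wavelengths)


def _participant_timeline(rng: np.random.Generator, spec: SyntheticSpec,
                          index: int) -> ConditionTimeline:
    """Two dynamic passes (wash, dry+hang, fold) - condition order
    counterbalanced across participants - followed by six static
    smelling trials in shuffled order."""
    order = (("fragranced", "unfragranced") if index % 2 == 0
             else ("unfragranced", "fragranced"))
    ranges = {"wash": spec.wash_duration, "dry_hang": spec.dry_hang_duration,
              "fold": spec.fold_duration}
    t = spec.lead_in_s
    intervals = []
    for cond in order:
        for task in ("wash", "dry_hang", "fold"):
            dur = rng.uniform(*ranges[task])
            intervals.append(Interval(f"{cond}_{task}", "dynamic", cond, task,
                                      t, t + dur))
            t += dur + rng.uniform(*spec.gap_duration)
    trials = [(c, f) for c in CONDITIONS for f in STATIC_TASKS]
    rng.shuffle(trials)
    for cond, form in trials:
        dur = rng.uniform(*spec.static_duration)
        intervals.append(Interval(f"{cond}_{form}", "static", cond, form,
                                  t, t + dur))
        t += dur + rng.uniform(*spec.gap_duration)
    return ConditionTimeline(intervals)


def _draw_events(rng: np.random.Generator, spec: SyntheticSpec,
                 timeline: ConditionTimeline, channel: int,
                 amp_scale: float) -> list[TrueEvent]:
    events: list[TrueEvent] = []
    for iv in timeline.intervals:
        rate = (spec.dynamic_event_rate if iv.phase == "dynamic"
                else spec.static_event_rate)
        amp_mult = 1.0
        if (channel in spec.effect_channels
                and iv.condition == spec.effect_condition):
            rate *= spec.effect_multiplier
            amp_mult = spec.effect_multiplier ** 0.5
        placed: list[tuple[float, float]] = []
        for _ in range(rng.poisson(rate)):
            # functional events are distinct episodes: keep them separated
            # (overlapping same-channel events are unidentifiable)
            for _try in range(30):
                dur = rng.uniform(*spec.event_duration)
                if dur > iv.duration:
                    dur = 0.8 * iv.duration
                onset = rng.uniform(iv.start, iv.end - dur)
                gap = spec.event_min_gap_s
                if all(onset + dur + gap <= o or o + d + gap <= onset
                       for o, d in placed):
                    placed.append((onset, dur))
                    amp = rng.normal(spec.event_amplitude_mean,
                                     spec.event_amplitude_sd)
                    amp = max(0.4, amp) * amp_scale * amp_mult
                    events.append(TrueEvent(onset, dur, amp, iv.phase,
                                            iv.task, iv.condition))
                    break
    return sorted(events, key=lambda e: e.onset)


def _evoked_response(events: list[TrueEvent], n: int, fs: float,
                     kernel: np.ndarray) -> np.ndarray:
    x = np.zeros(n)
    for ev in events:
        i0 = int(round(ev.onset * fs))
        nb = max(1, int(round(ev.duration * fs)))
        shape = np.convolve(np.ones(nb), kernel)
        shape /= shape.max()           # plateau == 1 => amplitude in uM
        seg = shape[:max(0, n - i0)]
        x[i0:i0 + len(seg)] += ev.amplitude * seg
    return x


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticStudy:
    """Generate the full study: recordings, timelines, questionnaire and
    ground truth, deterministic under ``spec.seed``."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    montage = _montage_subset(spec.n_channels)
    fs = spec.sampling_rate
    kernel = canonical_hrf(HRFParams(), fs)
    pp = PreprocessParams()

    recordings: dict[str, RawRecording] = {}
    timelines: dict[str, ConditionTimeline] = {}
    gt_events: dict[str, dict[int, list[TrueEvent]]] = {}
    gt_bad: dict[str, list[int]] = {}
    amp_scales: dict[str, float] = {}
    q_rows = []

    for idx in range(spec.n_participants):
        pid = f"P{idx + 1:02d}"
        timeline = _participant_timeline(rng, spec, idx)
        timelines[pid] = timeline
        n = int(round((timeline.intervals[-1].end + spec.tail_s) * fs))
        t = np.arange(n) / fs
        amp_scale = float(rng.normal(1.0, 0.1))
        amp_scales[pid] = amp_scale
        bad = sorted(int(c) for c in range(spec.n_channels)
                     if rng.uniform() < spec.fraction_bad)
        gt_bad[pid] = bad

        # participant-level physiology (global sources, shared phase)
        f_card = rng.uniform(*spec.cardiac_freq)
        f_resp = rng.uniform(*spec.resp_freq)
        f_mayer = max(0.05, rng.normal(spec.mayer_freq_mean,
                                       spec.mayer_freq_sd))
        ph = rng.uniform(0, 2 * np.pi, size=3)
        physio = (spec.cardiac_amp * np.sin(2 * np.pi * f_card * t + ph[0])
                  + spec.resp_amp * np.sin(2 * np.pi * f_resp * t + ph[1])
                  + spec.mayer_amp * np.sin(2 * np.pi * f_mayer * t + ph[2]))

        hbo = np.zeros((spec.n_channels, n))
        hbr = np.zeros((spec.n_channels, n))
        gt_events[pid] = {}
        for c in range(spec.n_channels):
            if c in bad:
                gt_events[pid][c] = []
                continue
            if spec.fixed_events is not None:
                evs = []
                for ch, onset, dur, amp in spec.fixed_events:
                    if ch != c:
                        continue
                    iv = min(timeline.intervals,
                             key=lambda iv: iv.distance(onset))
                    evs.append(TrueEvent(onset, dur, amp, iv.phase,
                                         iv.task, iv.condition))
            else:
                evs = _draw_events(rng, spec, timeline, c, amp_scale)
            gt_events[pid][c] = evs
            evoked = _evoked_response(evs, n, fs, kernel)
            gain = rng.uniform(0.8, 1.2)
            hbo[c] = evoked + gain * physio
            hbr[c] = spec.hbr_ratio * evoked + spec.hbr_noise_ratio * gain * physio

        od = concentration_to_od(hbo, hbr, montage, pp, fs).od
        # drift, white noise, motion artifacts live in OD space
        for c in range(spec.n_channels):
            n_spikes = rng.poisson(spec.spike_rate_per_min * n / fs / 60.0)
            spike_pos = rng.integers(0, n, size=n_spikes)
            spike_amp = (rng.uniform(*spec.spike_amplitude, size=n_spikes)
                         * rng.choice([-1.0, 1.0], size=n_spikes))
            spike_width = rng.integers(1, 4, size=n_spikes)
            n_shifts = rng.poisson(spec.shift_rate_per_min * n / fs / 60.0)
            shift_pos = rng.integers(0, n, size=n_shifts)
            shift_amp = rng.normal(0, spec.shift_amplitude, size=n_shifts)
            for w in range(2):
                if c in bad:
                    od[c, w] = rng.normal(0, spec.bad_channel_white_sd, n)
                else:
                    od[c, w] = od[c, w] + rng.normal(0, spec.od_white_sd, n)
                    wl_gain = rng.uniform(0.8, 1.2)
                    for p, a, wd in zip(spike_pos, spike_amp, spike_width):
                        od[c, w, p:p + wd] += a * wl_gain
                    for p, a in zip(shift_pos, shift_amp):
                        od[c, w, p:] += a * wl_gain
                od[c, w] += rng.normal(0, spec.od_drift_sd) * (t / t[-1])
        i0 = rng.uniform(0.5, 2.0, size=(spec.n_channels, 2))
        intensities = i0[:, :, None] * np.exp(-od)
        recordings[pid] = RawRecording(intensities, fs, montage, pid)

        for cond in CONDITIONS:
            for form in STATIC_TASKS:
                row = {"participant": pid, "condition": cond, "form": form}
                for attr, mean in QUESTIONNAIRE_MEANS[cond].items():
                    val = mean + rng.normal(0, spec.questionnaire_noise_sd)
                    if attr == "intensity" and cond == "fragranced":
                        val += spec.intensity_linkage * (amp_scale - 1.0)
                    lo, hi = (1, 5) if attr == "just_about_right" else (1, 9)
                    row[attr] = int(np.clip(round(val), lo, hi))
                q_rows.append(row)

    questionnaire = validate_questionnaire(pd.DataFrame(q_rows))
    gt = GroundTruth(events=gt_events, bad_channels=gt_bad,
                     amplitude_scale=amp_scales)
    return SyntheticStudy(recordings, timelines, questionnaire, gt, spec)


# ---------------------------------------------------------------------------
# Ground-truth manifest and recovery scoring
# ---------------------------------------------------------------------------

def truth_manifest(gt: GroundTruth, path) -> None:
    """JSON manifest sufficient to score event recovery."""
    obj = {
        "events": {pid: {str(c): [asdict(e) for e in evs]
                         for c, evs in by_ch.items()}
                   for pid, by_ch in gt.events.items()},
        "bad_channels": gt.bad_channels,
        "amplitude_scale": gt.amplitude_scale,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def load_manifest(path) -> GroundTruth:
    with open(path) as fh:
        obj = json.load(fh)
    events = {pid: {int(c): [TrueEvent(**e) for e in evs]
                    for c, evs in by_ch.items()}
              for pid, by_ch in obj["events"].items()}
    return GroundTruth(events=events,
                       bad_channels={p: list(v) for p, v in
                                     obj["bad_channels"].items()},
                       amplitude_scale=dict(obj["amplitude_scale"]))


def match_events(true_onsets, detected_onsets, tolerance: float
                 ) -> tuple[int, int, int]:
    """Greedy one-to-one matching by onset distance.

    Returns (n_matched, n_true, n_false_positive)."""
    true_left = list(true_onsets)
    n_true = len(true_left)
    n_det = len(detected_onsets)
    matched = 0
    for o in sorted(detected_onsets):
        if not true_left:
            break
        dist, best = min((abs(o - to), i) for i, to in enumerate(true_left))
        if dist <= tolerance:
            true_left.pop(best)
            matched += 1
    return matched, n_true, n_det - matched
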