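"""Reading and writing of study artefacts.

Recordings travel either as a minimal continuous-wave SNIRF subset (HDF5,
intensity + probe geometry + optional stimulus blocks) or as a documented
CSV dialect: first column ``time_s``, then one column per
(channel, wavelength) named ``chNN_wlMMM`` (e.g. ``ch03_wl760``), channels
in montage order, wavelengths in montage order within each channel.

Condition timelines, questionnaire scores and every result table are
tab-separated text with ``NA`` for missing values; time is seconds from
recording start with half-open condition intervals ``[start, end)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

PHASES = ("dynamic", "static")
CONDITIONS = ("fragranced", "unfragranced")
DYNAMIC_TASKS = ("wash", "dry_hang", "fold")
STATIC_TASKS = ("liquid", "wet", "dry")
TASKS = DYNAMIC_TASKS + STATIC_TASKS

QUESTIONNAIRE_ATTRIBUTES = ("liking", "intensity", "invigorating", "relaxing",
                            "just_about_right")
# attribute -> (scale minimum, scale maximum)
QUESTIONNAIRE_SCALES = {
    "liking": (1, 9),
    "intensity": (1, 9),
    "invigorating": (1, 9),
    "relaxing": (1, 9),
    "just_about_right": (1, 5),
}


class FormatError(ValueError):
    """A file does not conform to the declared on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Optode layout: labelled source/detector positions (mm) and channels.

    ``channels`` holds ``(source_label, detector_label, separation_mm)``
    triples; the order here defines channel order everywhere downstream.
    """

    sources: dict[str, tuple[float, float]]
    detectors: dict[str, tuple[float, float]]
    channels: list[tuple[str, str, float]]
    wavelengths: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self) -> None:
        if len(self.wavelengths) != 2:
            raise ValidationError("exactly two wavelengths are required")
        for s, d, sep in self.channels:
            if s not in self.sources:
                raise ValidationError(f"channel references unknown source {s!r}")
            if d not in self.detectors:
                raise ValidationError(f"channel references unknown detector {d!r}")
            if not sep > 0:
                raise ValidationError(f"non-positive separation for channel {s}-{d}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def default_montage() -> Montage:
    """The 20-channel prefrontal band: 8 sources and 7 detectors on two
    rows 30 mm apart, nearest neighbours paired at 30 mm separation."""
    top = ["S1", "D1", "S2", "D2", "S3", "D3", "S4"]
    bottom = ["D4", "S5", "D5", "S6", "D6", "S7", "D7", "S8"]
    sources: dict[str, tuple[float, float]] = {}
    detectors: dict[str, tuple[float, float]] = {}
    for i, lab in enumerate(top):
        (sources if lab.startswith("S") else detectors)[lab] = (30.0 * i, 30.0)
    for i, lab in enumerate(bottom):
        (sources if lab.startswith("S") else detectors)[lab] = (30.0 * i, 0.0)
    channels: list[tuple[str, str, float]] = []
    for row in (top, bottom):
        for a, b in zip(row, row[1:]):
            s, d = (a, b) if a.startswith("S") else (b, a)
            channels.append((s, d, 30.0))
    for a, b in zip(top, bottom):
        s, d = (a, b) if a.startswith("S") else (b, a)
        channels.append((s, d, 30.0))
    assert len(channels) == 20
    return Montage(sources=sources, detectors=detectors, channels=channels)


def _generic_montage(n_channels: int,
                     wavelengths: tuple[float, float]) -> Montage:
    """Placeholder geometry for CSV files, which carry no probe layout."""
    sources = {f"S{i+1}": (30.0 * i, 0.0) for i in range(n_channels)}
    detectors = {f"D{i+1}": (30.0 * i, 30.0) for i in range(n_channels)}
    channels = [(f"S{i+1}", f"D{i+1}", 30.0) for i in range(n_channels)]
    return Montage(sources, detectors, channels, wavelengths)


# ---------------------------------------------------------------------------
# Raw recording
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Per-channel, per-wavelength intensity series in detector units.

    ``intensities`` is indexed ``(channel, wavelength, time)`` with channel
    order equal to ``montage.channels`` and wavelength order equal to
    ``montage.wavelengths``.
    """

    intensities: np.ndarray
    sampling_rate: float
    montage: Montage
    participant_id: str = "P0"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be (channel, wavelength, time)")
        n_ch, n_wl, _ = self.intensities.shape
        if n_wl != 2:
            raise ValidationError("two wavelengths are required")
        if n_ch != self.montage.n_channels:
            raise ValidationError(
                f"{n_ch} channels in data but {self.montage.n_channels} in montage")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        bad = np.argwhere(~(self.intensities > 0))
        if bad.size:
            c, w, t = bad[0]
            raise ValidationError(
                f"non-positive intensity at channel {c}, wavelength index {w}, "
                f"sample {t}")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


# ---------------------------------------------------------------------------
# Condition timeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    label: str
    phase: str
    condition: str
    task: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if not self.start < self.end:
            raise ValidationError(
                f"interval {self.label!r}: start {self.start} >= end {self.end}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end

    def distance(self, t: float) -> float:
        if t < self.start:
            return self.start - t
        if t >= self.end:
            return t - self.end
        return 0.0


@dataclass
class ConditionTimeline:
    """Ordered, non-overlapping labelled intervals of the study protocol."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"intervals {a.label!r} and {b.label!r} overlap")

    def __len__(self) -> int:
        return len(self.intervals)

    def cells(self) -> list[tuple[str, str, str]]:
        """Distinct (phase, task, condition) cells in timeline order."""
        seen: list[tuple[str, str, str]] = []
        for iv in self.intervals:
            key = (iv.phase, iv.task, iv.condition)
            if key not in seen:
                seen.append(key)
        return seen

    def cell_duration(self, phase: str, task: str, condition: str) -> float:
        return sum(iv.duration for iv in self.intervals
                   if (iv.phase, iv.task, iv.condition) == (phase, task, condition))


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _csv_column(channel: int, wavelength: float) -> str:
    return f"ch{channel + 1:02d}_wl{int(round(wavelength))}"


def write_recording_csv(rec: RawRecording, path) -> None:
    cols = {"time_s": np.arange(rec.n_samples) / rec.sampling_rate}
    for c in range(rec.n_channels):
        for w, wl in enumerate(rec.montage.wavelengths):
            cols[_csv_column(c, wl)] = rec.intensities[c, w]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.15g")


def read_recording_csv(path, montage: Montage | None = None) -> RawRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("CSV recording must have a 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("recording must contain at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError("non-uniform time axis; resample before reading")
    # parse chNN_wlMMM columns, preserving first-appearance order
    chans: list[int] = []
    wls: list[float] = []
    for col in df.columns:
        if not col.startswith("ch"):
            continue
        try:
            ch_part, wl_part = col.split("_wl")
            ch = int(ch_part[2:]) - 1
            wl = float(wl_part)
        except ValueError as exc:
            raise FormatError(f"malformed column name {col!r}") from exc
        if ch not in chans:
            chans.append(ch)
        if wl not in wls:
            wls.append(wl)
    if len(wls) != 2:
        raise FormatError(f"expected 2 wavelength blocks, found {len(wls)}")
    if montage is None:
        montage = _generic_montage(len(chans), (wls[0], wls[1]))
    data = np.empty((len(chans), 2, len(t)))
    for ci, ch in enumerate(sorted(chans)):
        for wi, wl in enumerate(montage.wavelengths):
            col = _csv_column(ch, wl)
            if col not in df.columns:
                raise FormatError(f"missing wavelength block: column {col!r}")
            data[ci, wi] = df[col].to_numpy(dtype=float)
    bad = np.argwhere(~(data > 0))
    if bad.size:
        c, w, s = bad[0]
        raise ValidationError(
            f"non-positive intensity in channel {c}, wavelength index {w}, "
            f"sample {s}")
    fs = 1.0 / dt[0]
    return RawRecording(data, fs, montage)


# ---------------------------------------------------------------------------
# SNIRF subset
# ---------------------------------------------------------------------------

def write_recording_snirf(rec: RawRecording, path,
                          timeline: ConditionTimeline | None = None) -> None:
    """Write the minimal continuous-wave SNIRF subset.

    Layout: ``/nirs/data1`` holds the (time x measurement) series with one
    measurementList entry per (channel, wavelength); ``/nirs/probe`` holds
    2-D optode positions and labels; condition intervals, if given, become
    one ``/nirs/stimN`` block per interval label.
    """
    m = rec.montage
    src_labels = list(m.sources)
    det_labels = list(m.detectors)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.participant_id)
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        data = nirs.create_group("data1")
        series = rec.intensities.reshape(-1, rec.n_samples).T  # time x meas
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset(
            "time", data=np.arange(rec.n_samples) / rec.sampling_rate)
        k = 1
        for c, (s, d, _sep) in enumerate(m.channels):
            for w in range(2):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=src_labels.index(s) + 1)
                ml.create_dataset("detectorIndex", data=det_labels.index(d) + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(m.wavelengths))
        probe.create_dataset(
            "sourcePos2D", data=np.asarray([m.sources[s] for s in src_labels]))
        probe.create_dataset(
            "detectorPos2D", data=np.asarray([m.detectors[d] for d in det_labels]))
        probe.create_dataset("sourceLabels", data=src_labels)
        probe.create_dataset("detectorLabels", data=det_labels)
        if timeline is not None:
            for i, iv in enumerate(timeline.intervals, start=1):
                stim = nirs.create_group(f"stim{i}")
                stim.create_dataset(
                    "name", data=f"{iv.phase}|{iv.condition}|{iv.task}|{iv.label}")
                stim.create_dataset(
                    "data", data=np.asarray([[iv.start, iv.duration, 1.0]]))


def read_recording_snirf(path) -> tuple[RawRecording, ConditionTimeline | None]:
    with h5py.File(path, "r") as f:
        if "nirs" not in f or "data1" not in f["nirs"]:
            raise FormatError("not a SNIRF file: missing /nirs/data1")
        nirs = f["nirs"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])
        t = np.asarray(data["time"])
        if t.ndim != 1 or len(t) < 2:
            raise FormatError("SNIRF time axis must be an explicit vector")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise FormatError("non-uniform time axis; resample before reading")
        probe = nirs["probe"]
        wavelengths = tuple(np.asarray(probe["wavelengths"], dtype=float))
        if len(wavelengths) != 2:
            raise FormatError("expected exactly 2 wavelengths in probe block")
        src_labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in probe["sourceLabels"]]
        det_labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in probe["detectorLabels"]]
        spos = np.asarray(probe["sourcePos2D"], dtype=float)
        dpos = np.asarray(probe["detectorPos2D"], dtype=float)
        sources = {lab: tuple(p) for lab, p in zip(src_labels, spos)}
        detectors = {lab: tuple(p) for lab, p in zip(det_labels, dpos)}
        mls = sorted((k for k in data if k.startswith("measurementList")),
                     key=lambda k: int(k[len("measurementList"):]))
        if not mls:
            raise FormatError("missing measurementList blocks")
        pairs: list[tuple[str, str]] = []
        meas: dict[tuple[int, int], int] = {}
        for col, k in enumerate(mls):
            ml = data[k]
            s = src_labels[int(np.asarray(ml["sourceIndex"])) - 1]
            d = det_labels[int(np.asarray(ml["detectorIndex"])) - 1]
            w = int(np.asarray(ml["wavelengthIndex"])) - 1
            if (s, d) not in pairs:
                pairs.append((s, d))
            meas[(pairs.index((s, d)), w)] = col
        channels = []
        for s, d in pairs:
            sep = float(np.hypot(*(np.asarray(sources[s]) - np.asarray(detectors[d]))))
            channels.append((s, d, sep))
        montage = Montage(sources, detectors, channels,
                          (wavelengths[0], wavelengths[1]))
        n_ch, n_t = len(pairs), len(t)
        intens = np.empty((n_ch, 2, n_t))
        for (c, w), col in meas.items():
            intens[c, w] = series[:, col]
        sid = "P0"
        if "metaDataTags" in nirs and "SubjectID" in nirs["metaDataTags"]:
            raw = nirs["metaDataTags"]["SubjectID"][()]
            sid = raw.decode() if isinstance(raw, bytes) else str(raw)
        rec = RawRecording(intens, 1.0 / dt[0], montage, sid)
        stim_keys = sorted((k for k in nirs if k.startswith("stim")),
                           key=lambda k: int(k[len("stim"):]))
        timeline = None
        if stim_keys:
            ivs = []
            for k in stim_keys:
                raw = nirs[k]["name"][()]
                name = raw.decode() if isinstance(raw, bytes) else str(raw)
                phase, condition, task, label = name.split("|")
                for onset, dur, _amp in np.asarray(nirs[k]["data"], dtype=float):
                    ivs.append(Interval(label, phase, condition, task,
                                        onset, onset + dur))
            timeline = ConditionTimeline(ivs)
    return rec, timeline


def read_recording(path, format: str = "csv",
                   montage: Montage | None = None) -> RawRecording:
    """Read a raw recording; ``format`` is ``"snirf"`` or ``"csv"``."""
    if format == "csv":
        return read_recording_csv(path, montage)
    if format == "snirf":
        return read_recording_snirf(path)[0]
    raise ValueError(f"unknown format {format!r}")


def write_recording(rec: RawRecording, path, format: str = "csv",
                    timeline: ConditionTimeline | None = None) -> None:
    if format == "csv":
        write_recording_csv(rec, path)
    elif format == "snirf":
        write_recording_snirf(rec, path, timeline)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Timeline and questionnaire TSV
# ---------------------------------------------------------------------------

_TIMELINE_COLS = ["label", "phase", "condition", "task", "start", "end"]


def read_timeline(path) -> ConditionTimeline:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TIMELINE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"timeline missing columns: {missing}")
    intervals = [Interval(str(r.label), str(r.phase), str(r.condition),
                          str(r.task), float(r.start), float(r.end))
                 for r in df.itertuples(index=False)]
    return ConditionTimeline(intervals)


def write_timeline(timeline: ConditionTimeline, path) -> None:
    rows = [(iv.label, iv.phase, iv.condition, iv.task, iv.start, iv.end)
            for iv in timeline.intervals]
    pd.DataFrame(rows, columns=_TIMELINE_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.15g")


def validate_questionnaire(df: pd.DataFrame) -> pd.DataFrame:
    required = ["participant", "condition", "form", *QUESTIONNAIRE_ATTRIBUTES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"questionnaire missing columns: {missing}")
    for attr, (lo, hi) in QUESTIONNAIRE_SCALES.items():
        vals = df[attr].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise ValidationError(f"{attr} scores outside [{lo}, {hi}]")
    bad_form = set(df["form"]) - set(STATIC_TASKS)
    if bad_form:
        raise ValidationError(f"unknown questionnaire forms: {sorted(bad_form)}")
    if df.duplicated(["participant", "condition", "form"]).any():
        raise ValidationError("duplicate participant x condition x form rows")
    return df


def read_questionnaire(path) -> pd.DataFrame:
    return validate_questionnaire(
        pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False))


def write_questionnaire(df: pd.DataFrame, path) -> None:
    validate_questionnaire(df).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as TSV with ``NA`` for missing cells.

    Floats are printed with 15 significant digits so that a round trip
    reproduces every value to (at least) 12 significant digits.
    """
    if len(df) == 0:
        raise ValidationError("refusing to write an empty table")
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.15g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
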