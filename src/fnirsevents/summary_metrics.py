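"""Condition assignment and participant-level summary parameters.

Each detected event is assigned to the experimental condition whose
interval contains its onset (half-open [start, end)); onsets in gaps go
to the nearest interval, ties to the earlier one. Per
(participant, channel, phase, task, condition) cell with at least one
event the table holds:

    n_events  - event count ("Mean_ONSET" once averaged at group level)
    mean_dur  - mean event duration, s
    mean_t    - mean GLM t-value
    max_t     - maximum GLM t-value

plus each value divided by the participant's duration of that condition
cell in seconds (``*_norm`` columns). Cells with no events yield no row:
they are missing data, not zeros, which is what produces the varying
degrees of freedom in the downstream paired tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aide_events import FunctionalEvent
from .data_io import ConditionTimeline, Interval

PARAMETERS = ("n_events", "mean_dur", "mean_t", "max_t")
NORM_PARAMETERS = tuple(f"{p}_norm" for p in PARAMETERS)


def assign_to_condition(event: FunctionalEvent,
                        timeline: ConditionTimeline) -> Interval:
    """Interval whose condition the event belongs to (containment first,
    then minimal distance, ties to the earlier interval)."""
    if not timeline.intervals:
        raise ValueError("timeline is empty")
    for iv in timeline.intervals:
        if iv.contains(event.onset):
            return iv
    return min(timeline.intervals, key=lambda iv: (iv.distance(event.onset),
                                                   iv.start))


def summarize(events: list[FunctionalEvent], timeline: ConditionTimeline,
              participant: str) -> pd.DataFrame:
    """Build the per-cell parameter rows for one participant.

    Raises if an assigned condition cell has zero total duration.
    """
    buckets: dict[tuple[str, str, str], list[FunctionalEvent]] = {}
    for ev in events:
        iv = assign_to_condition(ev, timeline)
        buckets.setdefault((iv.phase, iv.task, iv.condition), []).append(ev)
    rows = []
    for (phase, task, condition), evs in sorted(buckets.items()):
        cell_dur = timeline.cell_duration(phase, task, condition)
        if cell_dur <= 0:
            raise ValueError(
                f"zero-duration condition cell {(phase, task, condition)}")
        durs = np.array([e.duration for e in evs])
        ts = np.array([e.t_value for e in evs])
        for channel in sorted({e.channel for e in evs}):
            sel = [e for e in evs if e.channel == channel]
            d = np.array([e.duration for e in sel])
            t = np.array([e.t_value for e in sel])
            row = {
                "participant": participant,
                "channel": channel,
                "phase": phase,
                "task": task,
                "condition": condition,
                "cell_duration_s": cell_dur,
                "n_events": len(sel),
                "mean_dur": float(d.mean()),
                "mean_t": float(t.mean()),
                "max_t": float(t.max()),
            }
            for p in PARAMETERS:
                row[f"{p}_norm"] = row[p] / cell_dur
            rows.append(row)
    cols = ["participant", "channel", "phase", "task", "condition",
            "cell_duration_s", *PARAMETERS, *NORM_PARAMETERS]
    return pd.DataFrame(rows, columns=cols)


def combine_param_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-participant tables into the study-level ParamTable."""
    non_empty = [t for t in tables if len(t)]
    if not non_empty:
        return pd.DataFrame(columns=["participant", "channel", "phase", "task",
                                     "condition", "cell_duration_s",
                                     *PARAMETERS, *NORM_PARAMETERS])
    return pd.concat(non_empty, ignore_index=True)
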