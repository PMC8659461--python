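"""Windowing and the 13 saccade/fixation features.

Per window, the seven saccade features (max/sd/mean of per-saccade
velocities, max/sd/mean of durations, saccade count) and six fixation
features (same statistics minus the count) are computed from the event
sequence.  Standard deviations use the sample (n-1) convention; the sd of
a single event is 0.  Event velocity is summarized by the event's mean
sample speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import FIXATION, SACCADE, EventSequence, EyeEvent

__all__ = [
    "WindowSpec",
    "FEATURE_NAMES",
    "window_events",
    "extract_features",
    "build_feature_table",
]

log = logging.getLogger(__name__)

FEATURE_NAMES = [
    "max_saccade_velocity",
    "sd_saccade_velocity",
    "avg_saccade_velocity",
    "max_saccade_duration",
    "sd_saccade_duration",
    "avg_saccade_duration",
    "n_saccades",
    "max_fixation_velocity",
    "sd_fixation_velocity",
    "avg_fixation_velocity",
    "max_fixation_duration",
    "sd_fixation_duration",
    "avg_fixation_duration",
]

META_COLUMNS = ["label", "subject_id", "window_index"]


@dataclass(frozen=True)
class WindowSpec:
    """Window length and stride in seconds; non-overlapping by default."""

    length: float = 30.0
    stride: float | None = None

    def __post_init__(self) -> None:
        stride = self.length if self.stride is None else self.stride
        object.__setattr__(self, "stride", stride)
        if not (0 < stride <= self.length):
            raise ValueError("stride must satisfy 0 < stride <= length")


def window_events(
    events: EventSequence,
    spec: WindowSpec,
    segment_start: float = 0.0,
    segment_duration: float | None = None,
) -> list[EventSequence]:
    """Tile the segment with consecutive windows and clip events at
    window boundaries (durations truncated, velocities untouched).

    A segment shorter than one window yields zero windows (warning logged).
    An event spanning a boundary appears in every window it overlaps with
    its clipped duration, so total duration is conserved across windows.
    """
    if segment_duration is None:
        if len(events) == 0:
            return []
        segment_duration = max(e.end_t for e in events) - segment_start
    # only windows that fit entirely in the segment
    n_windows = int(np.floor((segment_duration - spec.length + 1e-9) / spec.stride)) + 1
    if n_windows < 1:
        log.warning(
            "segment of %.3f s shorter than window of %.3f s: zero windows",
            segment_duration,
            spec.length,
        )
        return []
    out = []
    for w in range(n_windows):
        w0 = segment_start + w * spec.stride
        w1 = w0 + spec.length
        sub = EventSequence()
        for e in events:
            s = max(e.start_t, w0)
            t = min(e.end_t, w1)
            if t > s:
                sub.append(EyeEvent(e.kind, s, t, e.peak_velocity, e.mean_velocity))
        out.append(sub)
    return out


def _stats(values: np.ndarray) -> tuple[float, float, float]:
    """(max, sample sd, mean); sd of a single value is 0."""
    if len(values) == 0:
        return 0.0, 0.0, 0.0
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return float(np.max(values)), sd, float(np.mean(values))


def extract_features(window: EventSequence) -> dict[str, float]:
    """The 13 features of one window as an ordered dict.

    A window with zero saccades has features 1-7 equal to 0; an empty
    window (no events at all) is an error, distinct from zero saccades.
    """
    if len(window) == 0:
        raise ValueError("empty window: no events to featurize")
    sac = [e for e in window if e.kind == SACCADE]
    fix = [e for e in window if e.kind == FIXATION]
    sv = np.array([e.mean_velocity for e in sac])
    sd_ = np.array([e.duration for e in sac])
    fv = np.array([e.mean_velocity for e in fix])
    fd = np.array([e.duration for e in fix])
    s_vmax, s_vsd, s_vavg = _stats(sv)
    s_dmax, s_dsd, s_davg = _stats(sd_)
    f_vmax, f_vsd, f_vavg = _stats(fv)
    f_dmax, f_dsd, f_davg = _stats(fd)
    return dict(
        zip(
            FEATURE_NAMES,
            [
                s_vmax,
                s_vsd,
                s_vavg,
                s_dmax,
                s_dsd,
                s_davg,
                float(len(sac)),
                f_vmax,
                f_vsd,
                f_vavg,
                f_dmax,
                f_dsd,
                f_davg,
            ],
        )
    )


def build_feature_table(
    segment_events_list,
    spec: WindowSpec,
    labels,
    subject_ids,
    segment_starts=None,
    segment_duration: float | None = None,
) -> pd.DataFrame:
    """Feature table over all segments: one row per (segment, window).

    ``segment_events_list`` aligns with ``labels`` and ``subject_ids``.
    Columns are the 13 canonical feature names plus label, subject_id,
    window_index; the CSV round-trips losslessly.
    """
    rows = []
    widx = 0
    for i, events in enumerate(segment_events_list):
        start = 0.0 if segment_starts is None else segment_starts[i]
        for win in window_events(events, spec, start, segment_duration):
            if len(win) == 0:
                continue
            row = extract_features(win)
            row["label"] = int(labels[i])
            row["subject_id"] = int(subject_ids[i])
            row["window_index"] = widx
            widx += 1
            rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_NAMES + META_COLUMNS)
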