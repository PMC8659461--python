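"""Velocity computation and I-VT saccade/fixation segmentation.

The raw gaze signal is split into the two oculomotor event classes the
feature stage consumes: *fixations* (gaze holds a position; low velocity)
and *saccades* (rapid relocations; high velocity).  Segmentation is
velocity-threshold identification (I-VT): a sample whose instantaneous
speed meets the threshold is saccadic, otherwise fixational; contiguous
runs become events, and events shorter than a minimum duration are merged
or relabeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .trace import GazeTrace

__all__ = [
    "VelocitySeries",
    "EyeEvent",
    "EventSequence",
    "resample_trace",
    "compute_velocity",
    "segment_events",
    "otsu_velocity_threshold",
]

#: default limit on interpolating across missing runs, seconds
DEFAULT_MAX_GAP = 0.2

#: standard oculomotor duration floors, seconds
DEFAULT_MIN_FIXATION = 0.1
DEFAULT_MIN_SACCADE = 0.02

SACCADE = "saccade"
FIXATION = "fixation"


@dataclass
class VelocitySeries:
    """Per-sample gaze speed in px/s.

    ``v[i]`` is the speed over the interval (t[i-1], t[i]]; the first sample
    has no predecessor and is undefined (``defined[0]`` is False), as are
    samples adjacent to missing data.
    """

    t: np.ndarray
    v: np.ndarray
    defined: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class EyeEvent:
    kind: str  # "saccade" or "fixation"
    start_t: float
    end_t: float
    peak_velocity: float
    mean_velocity: float

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


class EventSequence(list):
    """A list of :class:`EyeEvent` with CSV serialization."""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": e.kind,
                    "start_t": e.start_t,
                    "end_t": e.end_t,
                    "duration": e.duration,
                    "peak_v": e.peak_velocity,
                    "mean_v": e.mean_velocity,
                }
                for e in self
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventSequence":
        df = pd.read_csv(path)
        return cls(
            EyeEvent(r.kind, r.start_t, r.end_t, r.peak_v, r.mean_v)
            for r in df.itertuples()
        )


def resample_trace(
    trace: GazeTrace, target_fs: float, max_gap: float = DEFAULT_MAX_GAP
) -> GazeTrace:
    """Linear interpolation onto a uniform grid at ``target_fs``.

    Grid samples that fall inside a missing run longer than ``max_gap``
    seconds stay missing rather than being bridged.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    ok = trace.valid & np.isfinite(trace.x) & np.isfinite(trace.y)
    if ok.sum() < 2:
        raise ValueError("resampling needs at least 2 valid samples")
    tv = trace.t[ok]
    new_t = np.arange(tv[0], tv[-1] + 0.5 / target_fs, 1.0 / target_fs)
    new_x = np.interp(new_t, tv, trace.x[ok])
    new_y = np.interp(new_t, tv, trace.y[ok])
    # invalidate grid points bridging a gap between valid samples > max_gap
    gap_idx = np.searchsorted(tv, new_t, side="left")
    gap_idx = np.clip(gap_idx, 1, len(tv) - 1)
    gap = tv[gap_idx] - tv[gap_idx - 1]
    interior = (new_t > tv[0]) & (new_t < tv[-1])
    bad = interior & (gap > max_gap) & ~np.isin(new_t, tv)
    new_valid = ~bad
    new_x[bad] = np.nan
    new_y[bad] = np.nan
    return GazeTrace(new_t, new_x, new_y, new_valid, fs=target_fs)


def compute_velocity(trace: GazeTrace) -> VelocitySeries:
    """Speed from adjacent positions: v_i = ||p_i - p_{i-1}|| / (t_i - t_{i-1}).

    Pairs that span a missing sample are undefined, as is the first sample.
    """
    if trace.n_valid < 2:
        raise ValueError("velocity needs at least 2 valid samples")
    dt = np.diff(trace.t)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps in trace")
    dx = np.diff(trace.x)
    dy = np.diff(trace.y)
    v = np.full(len(trace), np.nan)
    v[1:] = np.hypot(dx, dy) / dt
    defined = np.zeros(len(trace), dtype=bool)
    defined[1:] = trace.valid[1:] & trace.valid[:-1]
    v[~defined] = np.nan
    return VelocitySeries(trace.t.copy(), v, defined, trace.fs)


def otsu_velocity_threshold(vel: VelocitySeries) -> float:
    """Self-calibrating saccade threshold: Otsu split of the per-recording
    speed distribution (log-spaced histograms behave poorly with speeds at
    zero, so the split is on raw speed)."""
    v = vel.v[vel.defined]
    if len(v) == 0:
        raise ValueError("no defined velocity samples")
    if np.ptp(v) == 0:
        return float(v[0]) + 1.0
    return float(threshold_otsu(v, nbins=256))


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal runs of equal labels: list of (start, stop_exclusive, label)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    return out


def segment_events(
    vel: VelocitySeries,
    threshold: float | None = None,
    min_fixation: float = DEFAULT_MIN_FIXATION,
    min_saccade: float = DEFAULT_MIN_SACCADE,
) -> EventSequence:
    """I-VT segmentation of a velocity series into an event sequence.

    Samples with ``v >= threshold`` are saccadic, others fixational (the
    default threshold is the Otsu split of the speed distribution).
    Within each contiguous block of defined samples, runs become events;
    then, in order: saccades shorter than ``min_saccade`` are relabeled
    fixation (merging into their neighbors), and fixations shorter than
    ``min_fixation`` are relabeled saccade.  Sample i covers the interval
    (t[i-1], t[i]], so events partition the defined extent of the trace.
    """
    if threshold is None:
        threshold = otsu_velocity_threshold(vel)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not np.any(vel.defined):
        raise ValueError("velocity series has no defined samples")

    events = EventSequence()
    # contiguous blocks of defined samples
    idx = np.flatnonzero(vel.defined)
    block_start = [idx[0]]
    block_end = []
    for a, b in zip(idx[:-1], idx[1:]):
        if b != a + 1:
            block_end.append(a)
            block_start.append(b)
    block_end.append(idx[-1])

    for b0, b1 in zip(block_start, block_end):
        sel = slice(b0, b1 + 1)
        v = vel.v[sel]
        labels = np.where(v >= threshold, SACCADE, FIXATION)
        runs = _runs(labels)
        runs = _enforce_min_durations(runs, vel.t, b0, min_fixation, min_saccade)
        for s, e, kind in runs:
            sv = vel.v[b0 + s : b0 + e]
            events.append(
                EyeEvent(
                    kind=kind,
                    start_t=float(vel.t[b0 + s - 1]),
                    end_t=float(vel.t[b0 + e - 1]),
                    peak_velocity=float(np.max(sv)),
                    mean_velocity=float(np.mean(sv)),
                )
            )
    return events


def _enforce_min_durations(runs, t, b0, min_fixation, min_saccade):
    """Apply the minimum-duration rules then re-merge adjacent same-kind runs.

    Run (s, e) spans samples [s, e) of the block starting at absolute index
    b0; its duration is t[b0+e-1] - t[b0+s-1].
    """

    def dur(s, e):
        return t[b0 + e - 1] - t[b0 + s - 1]

    def relabel_pass(runs, kind, min_dur, other):
        out = [
            (s, e, other if (k == kind and dur(s, e) < min_dur) else k)
            for s, e, k in runs
        ]
        return _merge_adjacent(out)

    runs = relabel_pass(runs, SACCADE, min_saccade, FIXATION)
    runs = relabel_pass(runs, FIXATION, min_fixation, SACCADE)
    return runs


def _merge_adjacent(runs):
    merged = []
    for s, e, k in runs:
        if merged and merged[-1][2] == k:
            merged[-1] = (merged[-1][0], e, k)
        else:
            merged.append((s, e, k))
    return merged
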