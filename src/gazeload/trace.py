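"""Gaze-trace container and CSV interchange.

A :class:`GazeTrace` is the object every stage of the pipeline exchanges: a
timestamped series of pupil positions in pixels, with an explicit per-sample
validity flag.  Samples where the pupil could not be located (no face, no
circles, dropout) are kept in place with ``valid = False`` and NaN
coordinates rather than silently dropped, so downstream stages can reason
about gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GazeTrace"]

CSV_COLUMNS = ["t", "x", "y", "valid"]


@dataclass
class GazeTrace:
    """Timestamped (x, y) pupil-position series.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    x, y : array of float
        Pupil position in pixels; NaN where ``valid`` is False.
    valid : array of bool
        Per-sample validity flag.
    fs : float
        Nominal sampling rate in samples/second.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    fs: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.x) & np.isfinite(self.y)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("t, x, y, valid must have equal length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def duration(self) -> float:
        """Extent of the trace in seconds, counting one trailing sample period."""
        if len(self.t) == 0:
            return 0.0
        return float(self.t[-1] - self.t[0]) + 1.0 / self.fs

    def copy(self) -> "GazeTrace":
        return GazeTrace(
            self.t.copy(), self.x.copy(), self.y.copy(), self.valid.copy(), self.fs
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.x,
                "y": self.y,
                "valid": self.valid.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        """Write as CSV with header ``t,x,y,valid``."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "GazeTrace":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trace CSV missing columns: {missing}")
        t = df["t"].to_numpy(float)
        if fs is None:
            dt = np.median(np.diff(t)) if len(t) > 1 else 1.0 / 30.0
            fs = 1.0 / dt
        return cls(
            t,
            df["x"].to_numpy(float),
            df["y"].to_numpy(float),
            df["valid"].to_numpy(bool),
            fs=float(fs),
        )


@dataclass
class LabeledSegment:
    """One scenario segment of a simulated or recorded study.

    ``label`` is the binary cognitive-load class: 0 = baseline driving,
    1 = driving with the auditory one-back task.
    """

    trace: GazeTrace
    label: int
    subject_id: int
    segment_id: int
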