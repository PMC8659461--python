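"""Raw-window dataset preparation for the deep models.

Each labeled segment is cut into fixed-length windows of the raw (x, y)
signal.  The sequence models (CNN, LSTM) consume the channeled form
(N, S, 2); the autoencoder consumes the flattened form (N, 2S) — a 60 s
window at 30 samples/s flattens to 3600 values.  Windows may optionally be
decimated to a shorter length for CPU-scale training.  Normalization
centers each window per channel (absolute screen position carries no
class information) and scales all windows by one dataset-wide standard
deviation per channel, preserving the between-window amplitude
differences that saccade dynamics produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..events import resample_trace
from ..trace import LabeledSegment

__all__ = ["RawWindowDataset", "prepare_raw_windows"]


@dataclass
class RawWindowDataset:
    """Windows X with labels y and per-window subject ids.

    ``X`` is (N, S, 2) channeled or (N, 2S) flattened.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    fs: float
    window_s: float
    flattened: bool

    def __len__(self) -> int:
        return len(self.y)


def _impute(trace):
    """Fill missing samples by interpolation on the original time grid
    (edge values extended), preserving the sample count so every segment
    yields the same number of windows."""
    from ..trace import GazeTrace

    ok = trace.valid & np.isfinite(trace.x) & np.isfinite(trace.y)
    if ok.sum() < 2:
        raise ValueError("segment has fewer than 2 valid samples")
    x = np.interp(trace.t, trace.t[ok], trace.x[ok])
    y = np.interp(trace.t, trace.t[ok], trace.y[ok])
    return GazeTrace(trace.t, x, y, np.ones(len(trace), bool), fs=trace.fs)


def _decimate(w: np.ndarray, target_len: int) -> np.ndarray:
    """Linear-interpolation decimation of a (S, C) window to target_len."""
    S = w.shape[0]
    old = np.arange(S)
    new = np.linspace(0, S - 1, target_len)
    return np.column_stack([np.interp(new, old, w[:, c]) for c in range(w.shape[1])])


def prepare_raw_windows(
    segments: list[LabeledSegment],
    fs: float,
    window_s: float,
    flatten: bool = False,
    target_len: int | None = None,
    standardize: bool = True,
) -> RawWindowDataset:
    """Cut labeled segments into fixed-length raw windows.

    Segments whose native rate differs from ``fs`` or that contain missing
    samples are resampled/imputed by linear interpolation first.  All
    windows must come out the same length; ``target_len`` decimates each
    window (both channels) for scaled-down training.  ``standardize``
    applies the centering/global-scale normalization described above.
    """
    n_per = int(round(window_s * fs))
    if n_per < 2:
        raise ValueError("window too short at this sampling rate")
    Xs, ys, subs = [], [], []
    for seg in segments:
        trace = seg.trace
        if not trace.valid.all():
            trace = _impute(trace)
        if abs(trace.fs - fs) > 1e-9:
            trace = resample_trace(trace, fs, max_gap=np.inf)
        n_win = len(trace) // n_per
        for w in range(n_win):
            sl = slice(w * n_per, (w + 1) * n_per)
            win = np.column_stack([trace.x[sl], trace.y[sl]])
            if target_len is not None:
                win = _decimate(win, target_len)
            if standardize:
                win = win - win.mean(axis=0)
            Xs.append(win)
            ys.append(seg.label)
            subs.append(seg.subject_id)
    if not Xs:
        raise ValueError("no windows produced")
    lengths = {w.shape[0] for w in Xs}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent window lengths: {sorted(lengths)}")
    X = np.stack(Xs)
    if standardize:
        sd = X.std(axis=(0, 1))
        sd[sd == 0] = 1.0
        X = X / sd
    if flatten:
        # concatenate the x channel then the y channel
        X = np.concatenate([X[:, :, 0], X[:, :, 1]], axis=1)
    return RawWindowDataset(
        X=X,
        y=np.asarray(ys, dtype=int),
        subject_ids=np.asarray(subs, dtype=int),
        fs=fs,
        window_s=window_s,
        flattened=flatten,
    )
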