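"""Pupil-position extraction from facial image frames.

Pipeline per frame: locate the face region (detector on the first frame
and periodically, lightweight feature tracking in between), crop the
region, binarize at an intensity threshold, invert, take Sobel gradient
edges, and find the two strongest circles in the pupil radius range by
circular Hough transform; the gaze sample is the midpoint of the two
pupil centers.  Frames with no face or fewer than two circles yield
missing samples, so the output trace always has one sample per frame.

Coordinates are 0-based, origin top-left, x rightward, y downward; ROI
boxes are half-open [x, x+w) x [y, y+h).  The face detector is pluggable;
the built-in default finds the largest bright disk-like connected region,
which suffices for the schematic renderer (a pretrained cascade can be
bound for real video).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from skimage import measure
from skimage.feature import corner_peaks, corner_shi_tomasi, match_template
from skimage.filters import sobel, threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks

from .trace import GazeTrace

__all__ = [
    "Frame",
    "FaceROI",
    "PupilPair",
    "detect_face_roi",
    "track_face",
    "preprocess_roi",
    "detect_eye_circles",
    "extract_pupil_positions",
    "load_frames",
]

DEFAULT_BINARY_THRESHOLD = 0.5
DEFAULT_RADIUS_RANGE = (3, 8)
REDETECT_EVERY = 30  # frames between forced re-detections
MIN_TRACKED_FEATURES = 3


@dataclass
class Frame:
    """One grayscale frame with intensities in [0, 1]."""

    pixels: np.ndarray
    index: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 3:  # RGB -> luma
            px = px @ np.array([0.299, 0.587, 0.114])
        if px.size == 0:
            raise ValueError("empty frame")
        lo, hi = px.min(), px.max()
        if hi > 1.0:  # 0-255 inputs rescaled to [0, 1]
            px = px / 255.0
        if px.min() < 0 or px.max() > 1:
            raise ValueError("intensities must be in [0, 1]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class FaceROI:
    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ROI width and height must be positive")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI corner must be non-negative")

    def clipped(self, shape: tuple[int, int]) -> "FaceROI":
        H, W = shape
        x = max(0, min(self.x, W - 1))
        y = max(0, min(self.y, H - 1))
        return FaceROI(x, y, min(self.w, W - x), min(self.h, H - y))

    def crop(self, frame: Frame) -> np.ndarray:
        return frame.pixels[self.y : self.y + self.h, self.x : self.x + self.w]


@dataclass
class PupilPair:
    left: Optional[tuple[float, float]]
    right: Optional[tuple[float, float]]
    radii: tuple[float, float] = (0.0, 0.0)
    found: tuple[bool, bool] = (False, False)

    @property
    def midpoint(self) -> Optional[tuple[float, float]]:
        if self.left is None or self.right is None:
            return None
        return (
            (self.left[0] + self.right[0]) / 2.0,
            (self.left[1] + self.right[1]) / 2.0,
        )


FaceDetector = Callable[[Frame], Optional[FaceROI]]


def _blob_face_detector(frame: Frame, min_area: int = 64) -> Optional[FaceROI]:
    """Built-in detector: bounding box of the largest bright, reasonably
    disk-like connected region.  Returns None on blank frames."""
    binary = frame.pixels > DEFAULT_BINARY_THRESHOLD
    if not binary.any():
        return None
    labels = measure.label(binary)
    regions = [r for r in measure.regionprops(labels) if r.area >= min_area]
    if not regions:
        return None
    best = max(regions, key=lambda r: r.area)
    # disk-likeness: filled area fraction of the bounding box ~ pi/4 for a disk
    if best.extent < 0.4:
        return None
    y0, x0, y1, x1 = best.bbox
    return FaceROI(x0, y0, x1 - x0, y1 - y0).clipped(frame.shape)


def detect_face_roi(
    frame: Frame, detector: FaceDetector | None = None
) -> Optional[FaceROI]:
    """ROI of the most confident face, or None when no face is present.

    ``detector`` may bind any callable (e.g. a pretrained cascade); the
    default is the built-in bright-blob detector.
    """
    det = detector or _blob_face_detector
    roi = det(frame)
    return None if roi is None else roi.clipped(frame.shape)


def track_face(
    prev_roi: FaceROI,
    prev_frame: Frame,
    frame: Frame,
    min_features: int = MIN_TRACKED_FEATURES,
    search: int = 8,
    patch: int = 7,
) -> Optional[FaceROI]:
    """Propagate a face ROI by sparse corner-feature tracking.

    Shi-Tomasi corners inside the previous ROI are matched in the new frame
    by local template search; the ROI is translated by the median feature
    displacement.  Fewer than ``min_features`` confidently tracked features
    returns None, forcing re-detection.
    """
    prev = prev_roi.crop(prev_frame)
    if prev.size == 0 or np.ptp(frame.pixels) == 0:
        return None
    response = corner_shi_tomasi(prev)
    corners = corner_peaks(
        response, min_distance=5, threshold_rel=0.1, num_peaks=20
    )
    half = patch // 2
    H, W = frame.shape
    disps = []
    for cy, cx in corners:
        y = prev_roi.y + cy
        x = prev_roi.x + cx
        if not (half <= cy < prev.shape[0] - half and half <= cx < prev.shape[1] - half):
            continue
        tmpl = prev[cy - half : cy + half + 1, cx - half : cx + half + 1]
        if np.ptp(tmpl) == 0:
            continue
        y0 = max(0, y - half - search)
        y1 = min(H, y + half + search + 1)
        x0 = max(0, x - half - search)
        x1 = min(W, x + half + search + 1)
        window = frame.pixels[y0:y1, x0:x1]
        if window.shape[0] < patch or window.shape[1] < patch or np.ptp(window) == 0:
            continue
        score = match_template(window, tmpl)
        peak = np.unravel_index(np.argmax(score), score.shape)
        if score[peak] < 0.6:
            continue
        new_y = y0 + peak[0] + half
        new_x = x0 + peak[1] + half
        disps.append((new_x - x, new_y - y))
    if len(disps) < min_features:
        return None
    dx = int(round(float(np.median([d[0] for d in disps]))))
    dy = int(round(float(np.median([d[1] for d in disps]))))
    moved = FaceROI(
        max(0, prev_roi.x + dx), max(0, prev_roi.y + dy), prev_roi.w, prev_roi.h
    )
    return moved.clipped(frame.shape)


def preprocess_roi(
    frame: Frame, roi: FaceROI, threshold: float = DEFAULT_BINARY_THRESHOLD
) -> np.ndarray:
    """Binary edge map of the ROI: binarize, invert, Sobel, threshold.

    A pixel strictly above ``threshold`` is foreground before inversion.
    The Sobel gradient magnitude of the inverted binary image is
    thresholded by Otsu (a gradient-free ROI yields an empty map).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    crop = roi.crop(frame)
    if crop.size == 0 or crop.shape[0] < 2 or crop.shape[1] < 2:
        raise ValueError("degenerate ROI")
    binary = crop > threshold
    inverse = ~binary
    grad = sobel(inverse.astype(float))
    if np.ptp(grad) == 0:
        return np.zeros_like(grad, dtype=bool)
    return grad > threshold_otsu(grad)


def invert_binary(b: np.ndarray) -> np.ndarray:
    """Foreground/background inversion of a binary image (an involution)."""
    return ~np.asarray(b, dtype=bool)


def detect_eye_circles(
    edge_map: np.ndarray, radius_range: Sequence[int] = DEFAULT_RADIUS_RANGE
) -> PupilPair:
    """Two strongest circles under a circular Hough accumulator.

    Detected circles are assigned left/right by ascending x.  Fewer than
    two circles (or an empty edge map) set the corresponding found flags
    to False.
    """
    radii = np.arange(int(radius_range[0]), int(radius_range[-1]) + 1)
    if len(radii) == 0:
        raise ValueError("radius_range must be non-empty")
    if not edge_map.any():
        return PupilPair(None, None)
    accum = hough_circle(edge_map, radii)
    _, cx, cy, rad = hough_circle_peaks(
        accum,
        radii,
        total_num_peaks=2,
        min_xdistance=int(radii[-1]),
        min_ydistance=int(radii[-1]),
    )
    if len(cx) < 2:
        if len(cx) == 1:
            return PupilPair(
                (float(cx[0]), float(cy[0])), None, (float(rad[0]), 0.0), (True, False)
            )
        return PupilPair(None, None)
    order = np.argsort(cx)
    i, j = order[0], order[1]
    return PupilPair(
        left=(float(cx[i]), float(cy[i])),
        right=(float(cx[j]), float(cy[j])),
        radii=(float(rad[i]), float(rad[j])),
        found=(True, True),
    )


def extract_pupil_positions(
    frames: Sequence[Frame] | np.ndarray,
    fps: float = 30.0,
    threshold: float = DEFAULT_BINARY_THRESHOLD,
    radius_range: Sequence[int] = DEFAULT_RADIUS_RANGE,
    detector: FaceDetector | None = None,
    redetect_every: int = REDETECT_EVERY,
) -> GazeTrace:
    """Per-frame pupil midpoint as a gaze trace.

    The face is detected on the first frame and re-detected every
    ``redetect_every`` frames or whenever tracking fails; in between it is
    propagated by feature tracking.  Frames with no face or without two
    circles yield missing samples; the trace length always equals the
    frame count.
    """
    if isinstance(frames, np.ndarray) and frames.ndim == 3:
        frames = [
            Frame(frames[i], index=i, timestamp=i / fps) for i in range(len(frames))
        ]
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("empty frame sequence")

    n = len(frames)
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    roi: Optional[FaceROI] = None
    prev_frame: Optional[Frame] = None

    for i, fr in enumerate(frames):
        if roi is None or i % redetect_every == 0:
            roi = detect_face_roi(fr, detector)
        elif prev_frame is not None:
            tracked = track_face(roi, prev_frame, fr)
            roi = tracked if tracked is not None else detect_face_roi(fr, detector)
        prev_frame = fr
        if roi is None:
            continue
        try:
            edges = preprocess_roi(fr, roi, threshold)
        except ValueError:
            roi = None
            continue
        pair = detect_eye_circles(edges, radius_range)
        mid = pair.midpoint
        if mid is None:
            continue
        xs[i] = roi.x + mid[0]
        ys[i] = roi.y + mid[1]
        valid[i] = True

    t = np.array([f.timestamp for f in frames], dtype=float)
    if np.any(np.diff(t) <= 0):
        t = np.arange(n) / fps
    return GazeTrace(t, xs, ys, valid, fs=fps)


def load_frames(directory, fps: float = 30.0) -> list[Frame]:
    """Read a directory of numbered PNG/TIFF frames into Frame objects."""
    import imageio.v3 as iio

    paths = sorted(
        p
        for p in Path(directory).iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise ValueError(f"no PNG/TIFF frames found in {directory}")
    return [
        Frame(iio.imread(p), index=i, timestamp=i / fps)
        for i, p in enumerate(paths)
    ]
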