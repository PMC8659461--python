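"""Synthetic gaze traces, paired degraded channels, and schematic face frames.

The study design this package targets — ~30 drivers, 12 one-minute scenario
segments each, half baseline (class 0) and half with an auditory one-back
task (class 1) — used data that cannot be redistributed.  This module
generates traces with the statistical structure that design assumes, so the
whole pipeline (vision, segmentation, features, classifiers, evaluation) is
exercisable and testable without any download.

The generative model alternates fixation epochs (anchor position plus
AR(1)-correlated jitter) with saccade epochs (minimum-jerk displacement to a
new anchor).  Class separation is encoded in :class:`ClassParams`: higher
cognitive load means longer fixations and fewer, smaller saccades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trace import GazeTrace, LabeledSegment

__all__ = [
    "ClassParams",
    "GazeSimSpec",
    "FrameRenderSpec",
    "simulate_trace",
    "simulate_study",
    "degrade_trace",
    "render_frames",
    "map_trace_to_frame",
    "min_jerk_peak_velocity",
    "default_class_params",
]

# viewing field the simulated gaze wanders over (a road-scene-sized region)
VIEW_W = 640.0
VIEW_H = 480.0

# AR(1) correlation of fixation jitter; high correlation emulates slow ocular
# drift and keeps sample-to-sample velocity well below saccadic speeds
JITTER_RHO = 0.9


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters of one cognitive-load class.

    All durations in seconds, amplitudes/jitter in pixels, rate in
    saccades/second.
    """

    fixation_duration_mean: float
    fixation_duration_sd: float
    saccade_rate: float
    saccade_amplitude_mean: float
    saccade_amplitude_sd: float
    saccade_duration_mean: float
    fixation_jitter_sd: float

    def __post_init__(self) -> None:
        if self.fixation_duration_mean <= 0:
            raise ValueError("fixation_duration_mean must be > 0")
        if self.saccade_rate < 0:
            raise ValueError("saccade_rate must be >= 0")
        if self.saccade_amplitude_mean <= 0 or self.saccade_duration_mean <= 0:
            raise ValueError("saccade amplitude/duration means must be > 0")
        for name in ("fixation_duration_sd", "saccade_amplitude_sd", "fixation_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.saccade_duration_mean >= self.fixation_duration_mean:
            raise ValueError("saccade_duration_mean must be < fixation_duration_mean")


def default_class_params() -> tuple[ClassParams, ClassParams]:
    """Default (class 0, class 1) parameters.

    Baseline driving (class 0): short fixations, frequent large scanning
    saccades.  One-back task (class 1): longer fixations, fewer and smaller
    saccades — gaze concentrates under cognitive load.
    """
    class0 = ClassParams(
        fixation_duration_mean=0.25,
        fixation_duration_sd=0.08,
        saccade_rate=3.0,
        saccade_amplitude_mean=80.0,
        saccade_amplitude_sd=20.0,
        saccade_duration_mean=0.045,
        fixation_jitter_sd=1.5,
    )
    class1 = ClassParams(
        fixation_duration_mean=0.50,
        fixation_duration_sd=0.15,
        saccade_rate=1.5,
        saccade_amplitude_mean=50.0,
        saccade_amplitude_sd=15.0,
        saccade_duration_mean=0.035,
        fixation_jitter_sd=1.0,
    )
    return class0, class1


@dataclass(frozen=True)
class GazeSimSpec:
    """Design of a simulated two-class study.

    Defaults mirror the emulated study: 30 subjects x 12 scenario segments
    of 60 s (6 per class) at 30 samples/s; windowing at 30 s downstream
    yields 720 labeled windows, 360 per class.
    """

    n_subjects: int = 30
    segments_per_subject: int = 12
    segment_duration: float = 60.0
    segments_per_class: int = 6
    fs: float = 30.0
    class0: ClassParams = field(default_factory=lambda: default_class_params()[0])
    class1: ClassParams = field(default_factory=lambda: default_class_params()[1])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.segments_per_subject < 1:
            raise ValueError("n_subjects and segments_per_subject must be >= 1")
        if self.segments_per_class * 2 != self.segments_per_subject:
            raise ValueError("segments_per_class x 2 must equal segments_per_subject")
        if self.fs <= 0 or self.segment_duration <= 0:
            raise ValueError("fs and segment_duration must be > 0")


def min_jerk_peak_velocity(amplitude: float, duration: float) -> float:
    """Peak velocity (px/s) of a minimum-jerk displacement of given
    amplitude (px) and duration (s); the profile peaks at 1.875 x amp/dur."""
    return 1.875 * amplitude / duration


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by mirror reflection."""
    period = 2.0 * (hi - lo)
    v = (v - lo) % period
    return lo + min(v, period - v)


def _min_jerk(n: int) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on n samples, 0 -> 1."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_trace(
    params: ClassParams, duration: float, fs: float, seed: int
) -> GazeTrace:
    """Simulate a single gaze trace of ``floor(duration * fs)`` samples.

    Fixation epochs hold an anchor position with AR(1) jitter; saccade
    epochs move to a new anchor along a minimum-jerk profile.  Fixation
    durations are truncated normal draws from ``params``; whether a saccade
    follows a fixation is a Bernoulli draw with probability
    ``saccade_rate x mean cycle length`` (capped at 1), so the realised
    saccade rate honours ``params.saccade_rate`` up to the geometric cap.
    Same (params, duration, fs, seed) gives a bit-identical trace.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(math.floor(duration * fs))
    if n < 2:
        raise ValueError("duration x fs must give at least 2 samples")
    dt = 1.0 / fs

    cycle = params.fixation_duration_mean + params.saccade_duration_mean
    p_sacc = min(1.0, params.saccade_rate * cycle)

    xs = np.empty(n)
    ys = np.empty(n)
    ax = VIEW_W / 2.0
    ay = VIEW_H / 2.0
    i = 0
    while i < n:
        # fixation epoch
        d = rng.normal(params.fixation_duration_mean, params.fixation_duration_sd)
        n_fix = max(2, int(round(d * fs)))
        n_fix = min(n_fix, n - i)
        xs[i : i + n_fix] = ax
        ys[i : i + n_fix] = ay
        i += n_fix
        if i >= n:
            break
        if p_sacc <= 0.0 or rng.random() >= p_sacc:
            continue  # fixation continues at the same anchor
        # saccade epoch to a new anchor; the direction is rejection-sampled so
        # the landing point stays in the viewing field without shrinking the
        # drawn amplitude (reflection fallback only for oversized amplitudes)
        amp = max(1.0, rng.normal(params.saccade_amplitude_mean, params.saccade_amplitude_sd))
        for _ in range(64):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            tx = ax + amp * math.cos(ang)
            ty = ay + amp * math.sin(ang)
            if 0.0 <= tx <= VIEW_W and 0.0 <= ty <= VIEW_H:
                break
        else:
            tx = _reflect(tx, 0.0, VIEW_W)
            ty = _reflect(ty, 0.0, VIEW_H)
        d = rng.normal(params.saccade_duration_mean, 0.25 * params.saccade_duration_mean)
        n_sac = max(2, int(round(d * fs)))
        n_sac = min(n_sac, n - i)
        prof = _min_jerk(n_sac + 1)[1:]  # exclude the start point already emitted
        xs[i : i + n_sac] = ax + (tx - ax) * prof
        ys[i : i + n_sac] = ay + (ty - ay) * prof
        i += n_sac
        ax, ay = tx, ty

    # AR(1) jitter with stationary sd = fixation_jitter_sd
    sd = params.fixation_jitter_sd
    if sd > 0:
        innov_sd = sd * math.sqrt(1.0 - JITTER_RHO**2)
        for arr in (xs, ys):
            e = np.empty(n)
            e[0] = rng.normal(0.0, sd)
            innov = rng.normal(0.0, innov_sd, n - 1)
            for k in range(1, n):
                e[k] = JITTER_RHO * e[k - 1] + innov[k - 1]
            arr += e

    t = np.arange(n) * dt
    return GazeTrace(t, xs, ys, np.ones(n, dtype=bool), fs=fs)


def simulate_study(spec: GazeSimSpec) -> list[LabeledSegment]:
    """Simulate the full labeled study: one trace per (subject, segment).

    Each subject contributes ``segments_per_subject`` segments, exactly half
    per class, label order alternating within subject.  Per-segment seeds are
    derived deterministically from ``spec.seed``.
    """
    segments: list[LabeledSegment] = []
    for subj in range(spec.n_subjects):
        for seg in range(spec.segments_per_subject):
            label = seg % 2
            params = spec.class1 if label == 1 else spec.class0
            seed = np.random.SeedSequence(
                spec.seed, spawn_key=(subj, seg)
            ).generate_state(1)[0] % (2**31)
            trace = simulate_trace(params, spec.segment_duration, spec.fs, int(seed))
            segments.append(LabeledSegment(trace, label, subj, seg))
    return segments


def degrade_trace(
    trace: GazeTrace, noise_sd: float, dropout_prob: float, seed: int
) -> GazeTrace:
    """Produce the paired "camera" channel: additive Gaussian position noise
    plus random sample dropout (flagged invalid, not removed).

    ``noise_sd = 0`` and ``dropout_prob = 0`` return an identical copy.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (0.0 <= dropout_prob < 1.0):
        raise ValueError("dropout_prob must be in [0, 1)")
    out = trace.copy()
    rng = np.random.default_rng(seed)
    n = len(out)
    if noise_sd > 0:
        out.x = out.x + rng.normal(0.0, noise_sd, n)
        out.y = out.y + rng.normal(0.0, noise_sd, n)
    if dropout_prob > 0:
        drop = rng.random(n) < dropout_prob
        out.valid = out.valid & ~drop
        out.x[drop] = np.nan
        out.y[drop] = np.nan
    return out


@dataclass(frozen=True)
class FrameRenderSpec:
    """Geometry and intensities of the schematic face renderer.

    A bright face disk on a dark background with two dark pupil disks; the
    trace position is encoded as the midpoint of the two pupil centers.
    Intensities are gray levels in [0, 1].
    """

    width: int = 160
    height: int = 120
    face_center: tuple[float, float] = (80.0, 56.0)
    face_radius: float = 40.0
    eye_offset: tuple[float, float] = (14.0, -8.0)
    pupil_radius: float = 4.0
    background_level: float = 0.10
    skin_level: float = 0.80
    pupil_level: float = 0.05

    def __post_init__(self) -> None:
        if self.pupil_level >= self.skin_level:
            raise ValueError("pupils must be darker than the face")
        if self.pupil_radius < 2:
            raise ValueError("pupil_radius must be >= 2")
        dx, dy = self.eye_offset
        if math.hypot(dx, dy) + self.pupil_radius > self.face_radius:
            raise ValueError("eye disks must lie inside the face disk")

    @property
    def nominal_eye_midpoint(self) -> tuple[float, float]:
        cx, cy = self.face_center
        return (cx, cy + self.eye_offset[1])

    @property
    def gaze_travel_radius(self) -> float:
        """Largest eye-midpoint excursion that keeps pupils inside the face."""
        dx, dy = self.eye_offset
        return self.face_radius - math.hypot(dx, dy) - self.pupil_radius - 1.0


def _disk(img: np.ndarray, cx: float, cy: float, r: float, level: float) -> None:
    h, w = img.shape
    y0 = max(0, int(cy - r) - 1)
    y1 = min(h, int(cy + r) + 2)
    x0 = max(0, int(cx - r) - 1)
    x1 = min(w, int(cx + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1][(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = level


def render_frames(
    trace: GazeTrace, spec: FrameRenderSpec = FrameRenderSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Render one grayscale frame per trace sample.

    The trace (x, y) is taken as the eye midpoint in frame coordinates; the
    face disk follows it so that both pupils sit at ``eye_offset`` on either
    side.  Returns ``(frames, centers)`` where ``frames`` has shape
    (n, height, width) and ``centers[i] = (x, y)`` is the ground-truth pupil
    midpoint of frame i.  Raises if a pupil would leave the frame, naming
    the frame index.
    """
    dx, dy = spec.eye_offset
    n = len(trace)
    frames = np.full((n, spec.height, spec.width), spec.background_level)
    centers = np.column_stack([trace.x, trace.y])
    r = spec.pupil_radius
    for i in range(n):
        mx, my = centers[i]
        fc_x, fc_y = mx, my - dy
        for ex in (mx - dx, mx + dx):
            if not (r <= ex < spec.width - r and r <= my < spec.height - r):
                raise ValueError(f"pupil position outside frame at frame {i}")
        _disk(frames[i], fc_x, fc_y, spec.face_radius, spec.skin_level)
        _disk(frames[i], mx - dx, my, r, spec.pupil_level)
        _disk(frames[i], mx + dx, my, r, spec.pupil_level)
    return frames, centers


def map_trace_to_frame(
    trace: GazeTrace, spec: FrameRenderSpec = FrameRenderSpec()
) -> GazeTrace:
    """Recenter and scale a simulated trace into frame coordinates so the
    rendered pupils always stay inside the face disk."""
    out = trace.copy()
    mx0, my0 = spec.nominal_eye_midpoint
    cx = np.nanmean(out.x)
    cy = np.nanmean(out.y)
    dev = np.nanmax(np.hypot(out.x - cx, out.y - cy))
    scale = 1.0 if dev == 0 else min(1.0, spec.gaze_travel_radius / dev)
    out.x = mx0 + (out.x - cx) * scale
    out.y = my0 + (out.y - cy) * scale
    return out
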