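"""Synthetic sperm-motility sequences: tracks, rendered frames, detections.

The study's recordings are 25-frame, 768×576 px, 8-bit phase-contrast
sequences at 0.833 µm/px, containing cells from the three WHO motility
classes.  This module emulates them at three levels:

* ``simulate_tracks`` — ground-truth head trajectories.  Progressive cells
  keep a persistent heading perturbed by Gaussian noise and carry a
  sinusoidal lateral beat standing in for flagellar oscillation;
  non-progressive cells do a small-step random walk with strong turning;
  immotile cells stay put up to sub-pixel jitter.  The arena boundary is
  reflective.
* ``render_sequence`` — 8-bit frames with Gaussian background, an
  anti-aliased bright ellipse per head (oriented along the instantaneous
  heading) plus a surrounding bright halo annulus mimicking the
  phase-contrast artifact, and optional debris blobs.
* ``corrupt_detections`` — detection-level observations bypassing imaging:
  each true point survives with probability ``p_d`` and is jittered; Poisson
  clutter is added per frame.

All randomness is driven by explicit seeds, so fixed seeds give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import Point, Track
from .segmentation import FrameObservations
from .units import PIXEL_SIZE_UM

__all__ = [
    "MotionParams",
    "RenderParams",
    "CorruptionParams",
    "simulate_tracks",
    "render_sequence",
    "corrupt_detections",
]

#: Head ellipse axes in pixels (4.3 µm × 2.9 µm at 0.833 µm/px).
HEAD_AXES_PX = (5.2, 3.5)


@dataclass
class MotionParams:
    """Population and motion model parameters (pixels, frames, radians).

    ``class_fractions`` orders the WHO classes (progressive,
    non-progressive, immotile) and must sum to 1.  Per-class speed means and
    standard deviations are per-step draws in px/frame.  ``placement``
    selects random initial positions or a regular grid ("grid" spreads cells
    as far apart as the arena allows — useful for well-separated scenes).
    """

    n_cells: int = 20
    frame_count: int = 25
    class_fractions: tuple = (0.5, 0.25, 0.25)
    speed_mean: tuple = (4.0, 1.0, 0.0)
    speed_sd: tuple = (1.0, 0.5, 0.0)
    beat_amplitude: float = 1.5
    beat_frequency: float = 0.2
    heading_noise_sd: float = 0.15
    jitter_sd: float = 0.05
    width: int = 768
    height: int = 576
    margin: float = 20.0
    placement: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")


@dataclass
class RenderParams:
    """Appearance parameters for rendered frames (8-bit intensities)."""

    head_axes: tuple = HEAD_AXES_PX
    head_intensity: float = 120.0
    halo_radius: float = 5.5
    halo_intensity: float = 18.0
    background_mean: float = 40.0
    background_sd: float = 6.0
    n_debris: int = 0
    debris_radius: float = 8.0
    debris_intensity: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.head_intensity, self.halo_intensity, self.background_mean):
            if not (0 <= v <= 255):
                raise ValueError("intensities must lie in the 8-bit range")


@dataclass
class CorruptionParams:
    """Detection-level noise model: misses, jitter and Poisson clutter."""

    p_d: float = 1.0
    far_rate: float = 0.0
    jitter_sd: float = 0.0
    width: int = 768
    height: int = 576
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_d <= 1.0):
            raise ValueError("p_d must lie in [0, 1]")
        if self.far_rate < 0:
            raise ValueError("far_rate must be >= 0")


def _initial_positions(params: MotionParams, rng: np.random.Generator) -> np.ndarray:
    w, h, m = params.width, params.height, params.margin
    if params.placement == "grid":
        n = params.n_cells
        cols = int(math.ceil(math.sqrt(n * w / h)))
        rows = int(math.ceil(n / cols))
        xs = np.linspace(m, w - m, cols)
        ys = np.linspace(m, h - m, rows)
        pts = [(x, y) for y in ys for x in xs][:n]
        return np.array(pts, dtype=float)
    return np.column_stack([
        rng.uniform(m, w - m, params.n_cells),
        rng.uniform(m, h - m, params.n_cells),
    ])


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    v = (v - lo) % (2 * span)
    return lo + (span - abs(v - span))


def simulate_tracks(params: MotionParams) -> list:
    """Generate ground-truth tracks for one synthetic image sequence.

    Returns a list of gap-free :class:`Track` objects spanning all frames.
    Track ids are 1-based; the motility class of track ``i`` is
    ``tracks[i].motility_class`` ∈ {"progressive", "non_progressive",
    "immotile"}.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    fracs = np.asarray(params.class_fractions, dtype=float)
    # Deterministic class counts closest to the requested fractions.
    counts = np.floor(fracs * n).astype(int)
    while counts.sum() < n:
        counts[np.argmax(fracs * n - counts)] += 1
    classes = np.repeat(np.arange(3), counts)
    rng.shuffle(classes)

    pos = _initial_positions(params, rng)
    tracks = []
    names = ("progressive", "non_progressive", "immotile")
    for i in range(n):
        cls = int(classes[i])
        heading = rng.uniform(-math.pi, math.pi)
        phase = rng.uniform(0, 2 * math.pi)
        cx, cy = pos[i]
        pts = []
        for t in range(params.frame_count):
            if cls == 0:  # progressive: persistent heading + lateral beat
                if t > 0:
                    heading += rng.normal(0.0, params.heading_noise_sd)
                    speed = max(0.0, rng.normal(params.speed_mean[0], params.speed_sd[0]))
                    cx += speed * math.cos(heading)
                    cy += speed * math.sin(heading)
                beat = params.beat_amplitude * math.sin(
                    2 * math.pi * params.beat_frequency * t + phase
                )
                x = cx + beat * -math.sin(heading)
                y = cy + beat * math.cos(heading)
            elif cls == 1:  # non-progressive: strong-turning random walk
                if t > 0:
                    heading += rng.uniform(-math.pi / 2, math.pi / 2)
                    speed = max(0.0, rng.normal(params.speed_mean[1], params.speed_sd[1]))
                    cx += speed * math.cos(heading)
                    cy += speed * math.sin(heading)
                x, y = cx, cy
            else:  # immotile: sub-pixel jitter about a fixed point
                x = cx + rng.normal(0.0, params.jitter_sd)
                y = cy + rng.normal(0.0, params.jitter_sd)
            x = _reflect(x, 1.0, params.width - 2.0)
            y = _reflect(y, 1.0, params.height - 2.0)
            pts.append(Point(float(x), float(y)))
        track = Track(id=i + 1, birth_frame=0, points=pts)
        track.motility_class = names[cls]
        tracks.append(track)
    return tracks


def _heading_at(track: Track, t: int) -> float:
    pts = track.points
    if t + 1 < len(pts):
        a, b = pts[t], pts[t + 1]
    elif t > 0:
        a, b = pts[t - 1], pts[t]
    else:
        return 0.0
    dx, dy = b.x - a.x, b.y - a.y
    return math.atan2(dy, dx) if (dx or dy) else 0.0


def _add_ellipse(frame, cx, cy, a, b, phi, intensity):
    """Add an anti-aliased filled ellipse (semi-axes a, b, rotation phi)."""
    h, w = frame.shape
    r = max(a, b) + 1.5
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    u = dx * math.cos(phi) + dy * math.sin(phi)
    v = -dx * math.sin(phi) + dy * math.cos(phi)
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    cover = np.clip(1.5 * (1.0 - q) + 0.5, 0.0, 1.0)  # soft 1-px edge
    frame[y0:y1, x0:x1] += intensity * cover


def _add_annulus(frame, cx, cy, r_in, r_out, intensity):
    h, w = frame.shape
    r = r_out + 1.5
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rad = np.hypot(xx - cx, yy - cy)
    inner = np.clip(1.5 * (rad - r_in) + 0.5, 0.0, 1.0)
    outer = np.clip(1.5 * (r_out - rad) + 0.5, 0.0, 1.0)
    frame[y0:y1, x0:x1] += intensity * inner * outer


def render_sequence(
    tracks: Sequence[Track],
    params: Optional[RenderParams] = None,
    frame_count: Optional[int] = None,
    shape: tuple = (576, 768),
) -> np.ndarray:
    """Render tracks into a (T, H, W) uint8 phase-contrast-like stack."""
    params = params or RenderParams()
    if frame_count is None:
        frame_count = max(t.last_frame for t in tracks) + 1 if tracks else 1
    rng = np.random.default_rng(params.seed)
    h, w = shape
    a = params.head_axes[0] / 2.0
    b = params.head_axes[1] / 2.0
    debris = np.column_stack([
        rng.uniform(0, w, params.n_debris),
        rng.uniform(0, h, params.n_debris),
    ]) if params.n_debris else np.empty((0, 2))
    stack = np.empty((frame_count, h, w), dtype=np.uint8)
    for t in range(frame_count):
        frame = rng.normal(params.background_mean, params.background_sd, (h, w))
        for dx, dy in debris:
            _add_ellipse(frame, dx, dy, params.debris_radius,
                         params.debris_radius, 0.0, params.debris_intensity)
        for tr in tracks:
            p = tr.point_at(t)
            if p is None:
                continue
            phi = _heading_at(tr, t - tr.birth_frame)
            if params.halo_intensity > 0:
                _add_annulus(frame, p.x, p.y, max(a, b) + 0.5,
                             params.halo_radius, params.halo_intensity)
            _add_ellipse(frame, p.x, p.y, a, b, phi, params.head_intensity)
        stack[t] = np.clip(frame, 0, 255).astype(np.uint8)
    return stack


def corrupt_detections(
    tracks: Sequence[Track],
    params: CorruptionParams,
    frame_count: Optional[int] = None,
) -> list:
    """Detection-level observations: misses, positional jitter, clutter.

    Each true track point is kept independently with probability ``p_d``
    and perturbed by isotropic Gaussian jitter; ``Poisson(far_rate)``
    uniform clutter points are appended per frame.  Returns one
    :class:`FrameObservations` per frame.
    """
    if frame_count is None:
        frame_count = max(t.last_frame for t in tracks) + 1 if tracks else 0
    rng = np.random.default_rng(params.seed)
    frames = []
    for t in range(frame_count):
        pts = []
        for tr in tracks:
            p = tr.point_at(t)
            if p is None:
                continue
            if rng.uniform() < params.p_d:
                x = p.x + (rng.normal(0, params.jitter_sd) if params.jitter_sd else 0.0)
                y = p.y + (rng.normal(0, params.jitter_sd) if params.jitter_sd else 0.0)
                pts.append(Point(float(x), float(y)))
        for _ in range(rng.poisson(params.far_rate)):
            pts.append(Point(
                float(rng.uniform(0, params.width)),
                float(rng.uniform(0, params.height)),
            ))
        frames.append(FrameObservations(frame=t, centroids=pts))
    return frames
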