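"""Track representations, polar normalization, track distance and assignment.

Coordinates follow the raster convention: ``x`` is the column, ``y`` the row,
both 0-based with the origin at the image top-left, so ``y`` increases
downward.  All angles are measured in this frame consistently, so the
convention cancels out of every comparison.

A :class:`Track` is a time-indexed sequence of 2-D head positions.  Slots may
be *missing* (``None``) when the cell produced no usable detection in a
frame; interior gaps are filled by linear interpolation before any polar
computation.  The polar form of a track with ``L`` points is the sequence of
``L - 1`` (displacement, heading) steps; rotating a track so its first step
points along the +x axis ("normalization") removes the arbitrary initial
swimming direction and makes movement *patterns* comparable across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FORBIDDEN",
    "Point",
    "Track",
    "PolarTrack",
    "ReferenceLibrary",
    "wrap_angle",
    "to_polar",
    "normalize_track",
    "interpolate_missing",
    "track_distance",
    "solve_assignment",
]

#: Sentinel cost for forbidden assignment pairs.  Large but finite so the
#: underlying LAP solver stays numerically safe; pairs at or above half this
#: value are stripped from the returned assignment.
FORBIDDEN = 1e9


@dataclass(frozen=True)
class Point:
    """A 2-D position in pixels (x = column, y = row)."""

    x: float
    y: float

    def distance_to(self, other: "Point") -> float:
        return float(np.hypot(self.x - other.x, self.y - other.y))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class Track:
    """A time-indexed point sequence with explicit missing slots.

    Parameters
    ----------
    id : int
        Track identifier, unique within one association result.
    birth_frame : int
        0-based frame index of the first point.
    points : list of Point or None
        One slot per frame from ``birth_frame`` onward; ``None`` marks a
        frame with no assigned observation.
    miss_count : int
        Current run of consecutive missing observations (live tracks only).
    terminated : bool
        Whether the track has been closed by the lifecycle rules.
    """

    id: int
    birth_frame: int
    points: list = field(default_factory=list)
    miss_count: int = 0
    terminated: bool = False

    def __len__(self) -> int:
        return len(self.points)

    @property
    def last_frame(self) -> int:
        return self.birth_frame + len(self.points) - 1

    def frames(self) -> range:
        return range(self.birth_frame, self.birth_frame + len(self.points))

    def point_at(self, frame: int) -> Optional[Point]:
        if frame < self.birth_frame or frame > self.last_frame:
            return None
        return self.points[frame - self.birth_frame]

    def n_observed(self) -> int:
        """Number of non-missing points."""
        return sum(p is not None for p in self.points)

    def last_observed(self) -> tuple[int, Point]:
        """(frame, point) of the most recent non-missing slot."""
        for i in range(len(self.points) - 1, -1, -1):
            if self.points[i] is not None:
                return self.birth_frame + i, self.points[i]
        raise ValueError("track has no observed points")

    def first_observed(self) -> tuple[int, Point]:
        for i, p in enumerate(self.points):
            if p is not None:
                return self.birth_frame + i, p
        raise ValueError("track has no observed points")


@dataclass
class PolarTrack:
    """Step representation of a track: displacements and headings.

    ``d[i]`` is the Euclidean displacement (pixels) from point ``i`` to point
    ``i + 1`` and ``theta[i]`` its heading (radians) relative to the +x axis.
    Immotile steps (``d == 0``) carry ``theta == 0`` by convention.
    """

    d: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.d.shape != self.theta.shape or self.d.ndim != 1:
            raise ValueError("d and theta must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return len(self.d)


@dataclass
class ReferenceLibrary:
    """A bank of normalized exemplar polar tracks used as Softmax regions.

    Each exemplar carries the identifier of the image sequence it was
    extracted from so that the sequence under test can be held out
    (leave-one-out cross-validation).
    """

    tracks: list
    source_sequence_ids: list

    def __post_init__(self) -> None:
        if len(self.tracks) < 1:
            raise ValueError("reference library must contain at least one track")
        if len(self.tracks) != len(self.source_sequence_ids):
            raise ValueError("one source sequence id per track is required")
        for pt in self.tracks:
            if len(pt) >= 1 and abs(pt.theta[0]) > 1e-12 and pt.d[0] > 0:
                raise ValueError("library tracks must be normalized (first theta = 0)")
        # Padded arrays for vectorized distance computation.
        n = len(self.tracks)
        self.lengths = np.array([len(t) for t in self.tracks], dtype=int)
        m = int(self.lengths.max())
        self._d = np.zeros((n, m))
        self._theta = np.zeros((n, m))
        for i, t in enumerate(self.tracks):
            self._d[i, : len(t)] = t.d
            self._theta[i, : len(t)] = t.theta

    def __len__(self) -> int:
        return len(self.tracks)

    def step_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Padded (d, theta, lengths) arrays, one row per exemplar."""
        return self._d, self._theta, self.lengths


def wrap_angle(a):
    """Wrap angle(s) to the interval (−π, π]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(-a + np.pi, 2.0 * np.pi)
    w = np.pi - w
    return w if w.ndim else float(w)


def interpolate_missing(track: Track) -> Track:
    """Fill interior missing slots by linear interpolation.

    A run of ``k`` missing slots bounded by observed points is replaced by
    ``k`` dummy points evenly spaced on the segment joining the bounding
    points (``k + 1`` equal sub-steps), matching the dummy-point rule used
    everywhere a gapped track enters a distance computation.

    Raises
    ------
    ValueError
        If the track has leading or trailing missing slots (only interior
        gaps are interpolable).
    """
    pts = track.points
    if not pts:
        return Track(track.id, track.birth_frame, [], track.miss_count, track.terminated)
    if pts[0] is None or pts[-1] is None:
        raise ValueError("leading/trailing missing slots cannot be interpolated")
    out = list(pts)
    i = 0
    while i < len(out):
        if out[i] is None:
            j = i
            while out[j] is None:
                j += 1
            a, b = out[i - 1], out[j]
            k = j - i  # gap length
            for g in range(k):
                f = (g + 1) / (k + 1)
                out[i + g] = Point(a.x + f * (b.x - a.x), a.y + f * (b.y - a.y))
            i = j
        i += 1
    return Track(track.id, track.birth_frame, out, track.miss_count, track.terminated)


def to_polar(track: Track) -> PolarTrack:
    """Convert a gap-free track to its (displacement, heading) steps.

    Headings use the two-argument arctangent so the full quadrant is kept;
    a zero displacement yields heading 0.
    """
    pts = track.points
    if len(pts) < 2:
        raise ValueError("need at least 2 points for a polar representation")
    if any(p is None for p in pts):
        raise ValueError("interpolate missing slots before polar conversion")
    xy = np.array([[p.x, p.y] for p in pts], dtype=float)
    delta = np.diff(xy, axis=0)
    d = np.hypot(delta[:, 0], delta[:, 1])
    theta = np.arctan2(delta[:, 1], delta[:, 0])
    theta[d == 0] = 0.0
    return PolarTrack(d=d, theta=theta)


def normalize_track(polar: PolarTrack) -> PolarTrack:
    """Rotate a polar track so its first step points along the +x axis.

    Every heading is replaced by ``wrap(theta_i − theta_1)``; displacements
    are untouched.  Idempotent.  Steps with zero displacement keep heading 0.
    """
    if len(polar) < 1:
        raise ValueError("cannot normalize an empty polar track")
    # An immotile first step has no direction: the rotation angle is 0.
    theta0 = polar.theta[0] if polar.d[0] > 0 else 0.0
    theta = wrap_angle(polar.theta - theta0)
    theta = np.where(polar.d == 0, 0.0, theta)
    return PolarTrack(d=polar.d.copy(), theta=theta)


def track_distance(growing: PolarTrack, reference: PolarTrack, t: int) -> float:
    """Euclidean step-space distance between two polar tracks over t steps.

    The reference is truncated to its first ``t`` steps.  Angular differences
    are wrapped to (−π, π] so nearly identical headings straddling ±π do not
    incur a spurious 2π-scale penalty.

    Raises
    ------
    ValueError
        If either track has fewer than ``t`` steps ("not comparable"; the
        caller is expected to exclude such references).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if len(growing) < t or len(reference) < t:
        raise ValueError("track shorter than t steps is not comparable")
    dd = growing.d[:t] - reference.d[:t]
    dth = wrap_angle(growing.theta[:t] - reference.theta[:t])
    return float(np.sqrt(np.sum(dd * dd) + np.sum(dth * dth)))


def solve_assignment(cost: np.ndarray) -> dict:
    """Minimum-cost partial assignment of rows to columns.

    ``cost`` is a rectangular matrix of non-negative entries; forbidden pairs
    are encoded with :data:`FORBIDDEN` (or ``np.inf``, which is replaced by
    the sentinel internally).  The returned dict maps row index to column
    index using only finite-cost pairs; rows or columns whose every pair is
    forbidden remain unassigned.  Ties are broken deterministically by the
    underlying Hungarian-algorithm solver.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return {}
    safe = np.where(np.isfinite(cost), cost, FORBIDDEN)
    safe = np.minimum(safe, FORBIDDEN)
    rows, cols = linear_sum_assignment(safe)
    return {
        int(r): int(c)
        for r, c in zip(rows, cols)
        if safe[r, c] < FORBIDDEN / 2
    }
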