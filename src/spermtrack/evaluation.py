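"""Track-level scoring: optimal track pairing, P/R/F1, RMSE, miss threshold.

Estimated tracks are paired with ground-truth tracks by minimum-total-cost
assignment on their mean frame-aligned point distance.  A pairing is only
admissible when the two tracks overlap in time, their first and last points
lie within 25 pixels of each other, and the mean point distance over the
overlap stays within 50 pixels — matching spurious clutter tracks to real
targets at any cost is not tracking.  Accepted pairs count as correct
associations n_C, from which precision ``P = n_C/‖ω‖``, recall
``R = n_C/‖G‖`` and ``F1 = 2RP/(R+P) = 2·n_C/(‖ω‖+‖G‖)`` follow; the RMSE
of accepted pairs measures path precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .association import AssociationResult
from .geometry import Track, interpolate_missing, solve_assignment

__all__ = [
    "ENDPOINT_REJECT_PX",
    "MEAN_DISTANCE_REJECT_PX",
    "TrackMatch",
    "TrackingMetrics",
    "match_tracks",
    "precision_recall_f1",
    "score_association",
    "track_rmse",
    "required_miss_threshold",
]

#: Maximum allowed distance between the first (and last) points of a matched
#: track pair: d̄ = 5 allowed misses × 5 px per-step movement allowance.
ENDPOINT_REJECT_PX = 25.0
#: Maximum allowed mean frame-aligned point distance of a matched pair.
MEAN_DISTANCE_REJECT_PX = 50.0


@dataclass
class TrackMatch:
    """One accepted estimated↔truth track pairing."""

    estimated_id: int
    truth_id: int
    mean_point_distance: float
    endpoint_start_distance: float
    endpoint_end_distance: float
    accepted: bool


@dataclass
class TrackingMetrics:
    """Aggregate track-level scores for one association result."""

    n_C: int
    n_estimated: int
    n_truth: int
    precision: float
    recall: float
    f1: float
    mean_rmse: float = float("nan")


def _dense_points(track: Track) -> dict:
    """Frame → (x, y) over the track's lifespan, interior gaps interpolated."""
    filled = interpolate_missing(track)
    return {
        f: (p.x, p.y)
        for f, p in zip(filled.frames(), filled.points)
    }


def _pair_stats(est: Track, truth: Track):
    """(mean distance, start/end endpoint distances, overlap length) or None."""
    a, b = _dense_points(est), _dense_points(truth)
    overlap = sorted(set(a) & set(b))
    if not overlap:
        return None
    dists = [math.dist(a[f], b[f]) for f in overlap]
    _, ea = est.first_observed()
    _, eb = truth.first_observed()
    start = ea.distance_to(eb)
    _, la = est.last_observed()
    _, lb = truth.last_observed()
    end = la.distance_to(lb)
    return float(np.mean(dists)), start, end, len(overlap)


def match_tracks(
    estimated: "AssociationResult | Sequence[Track]",
    truth: Sequence[Track],
) -> list:
    """Optimal admissible pairing of estimated and ground-truth tracks.

    The pairing cost is the mean frame-aligned point distance over the
    temporal overlap; pairs with no overlap, endpoint distances above
    25 px, or mean distance above 50 px are forbidden.  The minimum-cost
    assignment over the admissible pairs yields the correct associations.
    """
    est_tracks = estimated.tracks if isinstance(estimated, AssociationResult) else list(estimated)
    truth = list(truth)
    if not est_tracks or not truth:
        return []
    cost = np.full((len(est_tracks), len(truth)), np.inf)
    stats: dict = {}
    for i, e in enumerate(est_tracks):
        for j, g in enumerate(truth):
            s = _pair_stats(e, g)
            if s is None:
                continue
            mean_d, start, end, _ = s
            if start > ENDPOINT_REJECT_PX or end > ENDPOINT_REJECT_PX:
                continue
            if mean_d > MEAN_DISTANCE_REJECT_PX:
                continue
            cost[i, j] = mean_d
            stats[i, j] = s
    sol = solve_assignment(cost)
    matches = []
    for i, j in sorted(sol.items()):
        mean_d, start, end, _ = stats[i, j]
        matches.append(
            TrackMatch(
                estimated_id=est_tracks[i].id,
                truth_id=truth[j].id,
                mean_point_distance=mean_d,
                endpoint_start_distance=start,
                endpoint_end_distance=end,
                accepted=True,
            )
        )
    return matches


def precision_recall_f1(n_C: int, n_estimated: int, n_truth: int) -> TrackingMetrics:
    """Precision, recall and F1 from the correct-association count.

    Both printed forms of the F1 definition — the harmonic mean of P and R,
    and ``2·n_C/(‖ω‖+‖G‖)`` — coincide; ``F1 = 0`` when ``P + R = 0``.
    """
    if n_C < 0 or n_C > min(n_estimated, n_truth):
        raise ValueError("n_C cannot exceed either set size")
    p = n_C / n_estimated if n_estimated > 0 else 0.0
    r = n_C / n_truth if n_truth > 0 else 0.0
    f1 = 2 * r * p / (r + p) if (r + p) > 0 else 0.0
    return TrackingMetrics(
        n_C=n_C, n_estimated=n_estimated, n_truth=n_truth,
        precision=p, recall=r, f1=f1,
    )


def track_rmse(a: Track, b: Track) -> float:
    """Root-mean-square point distance over the frame-aligned overlap.

    Interior gaps are interpolated first; the caller is responsible for
    rejecting pairs with no temporal overlap beforehand.
    """
    pa, pb = _dense_points(a), _dense_points(b)
    overlap = sorted(set(pa) & set(pb))
    if not overlap:
        raise ValueError("tracks have no temporal overlap")
    sq = [
        (pa[f][0] - pb[f][0]) ** 2 + (pa[f][1] - pb[f][1]) ** 2
        for f in overlap
    ]
    return float(math.sqrt(np.mean(sq)))


def score_association(
    estimated: AssociationResult,
    truth: Sequence[Track],
) -> TrackingMetrics:
    """Full track-level scorecard: pairing, P/R/F1 and mean RMSE."""
    truth = list(truth)
    matches = match_tracks(estimated, truth)
    metrics = precision_recall_f1(len(matches), len(estimated.tracks), len(truth))
    if matches:
        est_by_id = {t.id: t for t in estimated.tracks}
        truth_by_id = {t.id: t for t in truth}
        metrics.mean_rmse = float(np.mean([
            track_rmse(est_by_id[m.estimated_id], truth_by_id[m.truth_id])
            for m in matches
        ]))
    return metrics


def required_miss_threshold(p_d: float, pi: float = 0.99) -> int:
    """Smallest miss threshold d̄ observing a target with probability ≥ π.

    Under independent per-frame detections, a target is seen at least once
    in d̄ consecutive frames with probability ``1 − (1 − p_d)^d̄``; this
    returns the smallest integer d̄ making that at least ``pi``.
    """
    if not (0 < p_d < 1) or not (0 < pi < 1):
        raise ValueError("p_d and pi must lie strictly between 0 and 1")
    d_bar = max(1, math.ceil(math.log(1 - pi) / math.log(1 - p_d) - 1e-12))
    while 1 - (1 - p_d) ** d_bar < pi:  # guard against float boundary error
        d_bar += 1
    return int(d_bar)
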