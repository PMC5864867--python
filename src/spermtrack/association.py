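"""Probabilistic data association over a library of exemplar tracks.

The tracker treats data association as inference in a hybrid dynamic
Bayesian network.  A bank of N manually extracted, normalized exemplar
tracks plays the role of the N regions of a Softmax conditional probability
distribution: the region weights are a softmax of negative step-space
distances between the growing track and each (truncated) exemplar, so
exemplars whose movement pattern resembles the track so far dominate.  Each
region then scores the gated candidate observations with an isotropic
bivariate Gaussian in (displacement, heading) space centred on the
exemplar's own next step, with covariance ``λ·d·I`` growing with the
exemplar's step length (a wrapped-normal surrogate on the angular axis).
Region-conditional candidate scores are normalized per region and mixed by
the region weights, giving one probability per candidate.

Per frame, candidate probabilities for every live track feed a single
rectangular assignment problem (cost = −log probability, plus one explicit
MISS column per track), solved by the Hungarian algorithm so that no
observation serves two tracks.  Track lifecycle — births from unassigned
observations, a consecutive-miss counter, termination at the miss threshold
d̄ — follows the single-scan forward recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .geometry import (
    FORBIDDEN,
    Point,
    PolarTrack,
    ReferenceLibrary,
    Track,
    interpolate_missing,
    normalize_track,
    solve_assignment,
    to_polar,
    track_distance,
    wrap_angle,
)
from .segmentation import FrameObservations

__all__ = [
    "MISS",
    "GatingParams",
    "SoftmaxModel",
    "CandidateSet",
    "AssociationResult",
    "NoReferenceError",
    "gate_candidates",
    "region_weights",
    "candidate_density",
    "candidate_probabilities",
    "assign_frame",
    "step_lifecycle",
    "run_association",
    "build_reference_library",
    "validate_result",
    "max_step_displacement",
]

#: Sentinel returned in assignments for a track that received no observation.
MISS = "MISS"


class NoReferenceError(RuntimeError):
    """No exemplar track is long enough to be compared at the current step."""


@dataclass
class GatingParams:
    """Gating and lifecycle parameters.

    ``v_bar`` is the maximum directional speed of the targets in
    pixels/frame: after ``k`` consecutive misses a track accepts candidates
    strictly within radius ``(k+1)·v_bar`` of its last assigned point.
    ``d_bar`` is the maximum allowed run of consecutive missing observations
    before termination.
    """

    v_bar: float
    d_bar: int = 5

    def __post_init__(self) -> None:
        if self.v_bar <= 0:
            raise ValueError("v_bar must be positive")
        if self.d_bar < 1:
            raise ValueError("d_bar must be >= 1")


@dataclass
class SoftmaxModel:
    """Softmax-CPD association model over a reference library.

    The ``lambda_`` coefficient sets how fast the per-region Gaussian
    broadens with the exemplar's step length (Σ = λ·d·I); ``sigma_floor``
    bounds the variance away from zero for immotile exemplar steps.
    ``p_miss`` is the fixed probability mass of the explicit MISS option in
    the joint assignment.
    """

    library: ReferenceLibrary
    lambda_: float = 0.25
    sigma_floor: float = 0.25
    p_miss: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.sigma_floor <= 0:
            raise ValueError("lambda_ and sigma_floor must be positive")
        if not (0 < self.p_miss < 1):
            raise ValueError("p_miss must be in (0, 1)")


@dataclass
class CandidateSet:
    """Gated observations for one track at one frame.

    ``members`` holds ``(observation index, d, theta)`` with the
    displacement taken from the track's last assigned point and the heading
    rotated into the track's normalized frame.  The MISS option is implicit.
    """

    track_id: int
    frame: int
    members: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AssociationResult:
    """Confirmed tracks plus the false-alarm set τ₀."""

    tracks: list
    false_alarms: list  # list of (frame, Point)

    @property
    def K(self) -> int:
        return len(self.tracks)


def max_step_displacement(tracks: Sequence[Track]) -> float:
    """Largest single-frame displacement across tracks (a v̄ estimator).

    Interior gaps are interpolated first so a k-frame jump counts as k
    steps.  Helper for deriving the gate speed from a ground-truth table.
    """
    best = 0.0
    for tr in tracks:
        if tr.n_observed() < 2:
            continue
        polar = to_polar(interpolate_missing(tr))
        best = max(best, float(polar.d.max()))
    return best


# ---------------------------------------------------------------------------
# Candidate construction and scoring
# ---------------------------------------------------------------------------

def _observed_prefix(track: Track) -> Track:
    """Track truncated at its last observed slot (drops trailing misses)."""
    last_f, _ = track.last_observed()
    n = last_f - track.birth_frame + 1
    return Track(track.id, track.birth_frame, list(track.points[:n]))


def _growing_polar(track: Track) -> Optional[PolarTrack]:
    """Normalized polar steps of a live track, or None for 1-point tracks."""
    prefix = _observed_prefix(track)
    if prefix.n_observed() < 2:
        return None
    return normalize_track(to_polar(interpolate_missing(prefix)))


def _rotation_angle(track: Track) -> float:
    """Raw heading of the track's first motile step (its normalization angle)."""
    prefix = _observed_prefix(track)
    if prefix.n_observed() < 2:
        return 0.0
    polar = to_polar(interpolate_missing(prefix))
    motile = np.nonzero(polar.d > 0)[0]
    return float(polar.theta[motile[0]]) if len(motile) else 0.0


def gate_candidates(track: Track, obs: FrameObservations, params: GatingParams) -> CandidateSet:
    """Observations strictly within the track's current gate circle.

    The gate is centred on the last assigned point with radius
    ``(t − t_l)·v_bar`` where ``t − t_l = miss_count + 1`` is the number of
    frames since the last assignment.  Each member is converted to polar
    coordinates relative to that point and rotated into the track's
    normalized frame so it is commensurate with the library exemplars.
    """
    if track.terminated:
        raise ValueError("cannot gate candidates for a terminated track")
    if track.miss_count >= params.d_bar:
        raise ValueError("track exceeds the miss threshold and must be terminated")
    _, last = track.last_observed()
    radius = (track.miss_count + 1) * params.v_bar
    rot = _rotation_angle(track)
    members = []
    for j, p in enumerate(obs.centroids):
        dx, dy = p.x - last.x, p.y - last.y
        d = math.hypot(dx, dy)
        if d < radius:
            theta = math.atan2(dy, dx) if d > 0 else 0.0
            theta = float(wrap_angle(theta - rot)) if d > 0 else 0.0
            members.append((j, d, theta))
    return CandidateSet(track_id=track.id, frame=obs.frame, members=members)


def region_weights(growing: PolarTrack, library: ReferenceLibrary, t: int) -> np.ndarray:
    """Softmax region weights over the N library exemplars at step count t.

    Weight r is ``exp(−dist(Γ_t, τ_r(t)))`` normalized over the comparable
    exemplars; exemplars shorter than ``t`` steps are excluded and receive
    weight exactly 0.  Computed in log space for stability.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if len(growing) < t:
        raise ValueError("growing track has fewer than t steps")
    d_lib, th_lib, lengths = library.step_arrays()
    ok = lengths >= t
    if not ok.any():
        raise NoReferenceError(f"no library track has >= {t} steps")
    dd = growing.d[:t][None, :] - d_lib[ok, :t]
    dth = wrap_angle(growing.theta[:t][None, :] - th_lib[ok, :t])
    dist = np.sqrt(np.sum(dd * dd, axis=1) + np.sum(dth * dth, axis=1))
    log_w = -dist - logsumexp(-dist)
    weights = np.zeros(len(library))
    weights[ok] = np.exp(log_w)
    return weights


def candidate_density(
    candidate: tuple,
    region_step: tuple,
    lambda_: float,
    sigma_floor: float = 0.25,
) -> float:
    """Gaussian score of one candidate step under one exemplar's next step.

    Isotropic bivariate normal in (d, θ) with mean at the exemplar step and
    variance ``max(λ·d_r, sigma_floor)`` on both axes; the angular residual
    is wrapped to (−π, π] (wrapped-normal surrogate).
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    d, theta = candidate
    d_r, theta_r = region_step
    var = max(lambda_ * d_r, sigma_floor)
    dd = d - d_r
    dth = float(wrap_angle(theta - theta_r))
    return float(math.exp(-(dd * dd + dth * dth) / (2.0 * var)) / (2.0 * math.pi * var))


def _log_candidate_density(cand_d, cand_th, d_r, theta_r, lambda_, sigma_floor):
    """Vectorized log of candidate_density over candidate arrays."""
    var = max(lambda_ * d_r, sigma_floor)
    dd = cand_d - d_r
    dth = wrap_angle(cand_th - theta_r)
    with np.errstate(over="ignore"):  # huge residuals legitimately -> -inf
        return -(dd * dd + dth * dth) / (2.0 * var) - math.log(2.0 * math.pi * var)


def candidate_probabilities(
    cands: CandidateSet,
    growing: PolarTrack,
    model: SoftmaxModel,
    t: int,
) -> np.ndarray:
    """Mixture probability of each gated candidate being the next track point.

    For each comparable exemplar (one with at least ``t + 1`` steps, so both
    a length-``t`` prefix and a next step exist) the candidate densities are
    normalized to a per-region distribution; the output mixes these with the
    softmax region weights and sums to 1 over the candidates.  A region whose
    densities all underflow to zero contributes a uniform distribution.
    """
    m = len(cands)
    if m < 1:
        raise ValueError("need at least one candidate")
    d_lib, th_lib, lengths = model.library.step_arrays()
    ok = lengths >= t + 1
    if not ok.any():
        raise NoReferenceError(f"no library track has >= {t + 1} steps")
    # Region weights restricted to exemplars that also have a next step.
    sub = ReferenceLibrary(
        tracks=[model.library.tracks[i] for i in np.nonzero(ok)[0]],
        source_sequence_ids=[model.library.source_sequence_ids[i] for i in np.nonzero(ok)[0]],
    )
    w = region_weights(growing, sub, t)
    cand_d = np.array([c[1] for c in cands.members])
    cand_th = np.array([c[2] for c in cands.members])
    probs = np.zeros(m)
    for r, lib_idx in enumerate(np.nonzero(ok)[0]):
        if w[r] == 0.0:
            continue
        logp = _log_candidate_density(
            cand_d, cand_th, d_lib[lib_idx, t], th_lib[lib_idx, t],
            model.lambda_, model.sigma_floor,
        )
        norm = logsumexp(logp)
        if np.isfinite(norm):
            probs += w[r] * np.exp(logp - norm)
        else:  # total underflow: uniform fallback for this region
            probs += w[r] / m
    total = probs.sum()
    return probs / total if total > 0 else np.full(m, 1.0 / m)


# ---------------------------------------------------------------------------
# Frame assignment and lifecycle
# ---------------------------------------------------------------------------

class HDBNScorer:
    """Per-track candidate costs from the Softmax-CPD mixture."""

    def __init__(self, model: SoftmaxModel):
        self.model = model

    def costs(self, track: Track, cands: CandidateSet, params: GatingParams):
        m = len(cands)
        miss_cost = -math.log(self.model.p_miss)
        if m == 0:
            return np.empty(0), miss_cost
        growing = _growing_polar(track)
        probs = None
        if growing is not None:
            # Candidates appended after k misses span k+1 interpolated steps;
            # score the per-step displacement against the exemplar's next step.
            k = track.miss_count
            eff = CandidateSet(
                cands.track_id,
                cands.frame,
                [(j, d / (k + 1), th) for j, d, th in cands.members],
            )
            try:
                probs = candidate_probabilities(eff, growing, self.model, len(growing))
            except NoReferenceError:
                probs = None
        if probs is None:
            # Bootstrap prior for 1-point tracks (no movement pattern yet)
            # or when every exemplar is too short: distance-only Gaussian
            # score with scale v̄/2.  Deliberately *not* normalized over the
            # candidate set: the absolute displacement plausibility is what
            # lets the joint solver arbitrate between a young track and a
            # confirmed track competing for the same observation.
            sigma = params.v_bar / 2.0
            d = np.array([c[1] for c in cands.members])
            return (d * d) / (2.0 * sigma * sigma), miss_cost
        return -np.log(np.clip(probs, 1e-300, None)), miss_cost


class NNFScorer:
    """Euclidean-distance costs: the global nearest-neighbour baseline.

    The predicted position is the last assigned point (zero-velocity
    prediction).  The miss cost equals the current gate radius, so any gated
    observation is preferred over a miss.
    """

    def costs(self, track: Track, cands: CandidateSet, params: GatingParams):
        miss_cost = (track.miss_count + 1) * params.v_bar
        d = np.array([c[1] for c in cands.members])
        return d, miss_cost


def assign_frame(
    states: Sequence[Track],
    obs: FrameObservations,
    model: SoftmaxModel,
    params: GatingParams,
    scorer=None,
):
    """Jointly assign the frame's observations to the live tracks.

    Builds one rectangular cost matrix with a column per observation (cost
    = −log candidate probability for gated pairs, forbidden otherwise) and
    one private MISS column per track, then solves it with the Hungarian
    algorithm so no observation is used twice.

    Returns
    -------
    assignment : dict
        Track id → observation index, or :data:`MISS`.
    unassigned : list of int
        Indices of observations not assigned to any track.
    """
    if scorer is None:
        scorer = HDBNScorer(model)
    live = [t for t in states if not t.terminated]
    n_obs = obs.count
    assignment = {t.id: MISS for t in live}
    if live:
        cost = np.full((len(live), n_obs + len(live)), FORBIDDEN)
        for i, track in enumerate(live):
            cands = gate_candidates(track, obs, params)
            cand_costs, miss_cost = scorer.costs(track, cands, params)
            for (j, _, _), c in zip(cands.members, cand_costs):
                cost[i, j] = min(c, FORBIDDEN / 4)
            cost[i, n_obs + i] = miss_cost
        sol = solve_assignment(cost)
        for i, track in enumerate(live):
            j = sol.get(i)
            if j is not None and j < n_obs:
                assignment[track.id] = j
    used = {j for j in assignment.values() if j is not MISS}
    unassigned = [j for j in range(n_obs) if j not in used]
    return assignment, unassigned


def step_lifecycle(
    states: list,
    assignment: dict,
    unassigned: Sequence[int],
    obs: FrameObservations,
    frame: int,
    params: GatingParams,
    next_id: int,
):
    """Apply one frame's assignment to the track set.

    Assigned tracks append the observation and reset their miss counter;
    missed tracks append a missing slot and increment it, terminating at the
    d̄ threshold (trailing missing slots trimmed).  Each unassigned
    observation seeds a tentative single-point track.  Tentative tracks that
    die before gaining a second point are routed to the false-alarm set.

    Returns ``(live, finished, false_alarms, next_id)``.
    """
    live, finished, false_alarms = [], [], []
    for track in states:
        j = assignment.get(track.id, MISS)
        if j is not MISS:
            track.points.append(obs.centroids[j])
            track.miss_count = 0
            live.append(track)
        else:
            track.points.append(None)
            track.miss_count += 1
            if track.miss_count >= params.d_bar:
                track = _terminate(track)
                if track.n_observed() >= 2:
                    finished.append(track)
                else:
                    f, p = track.first_observed()
                    false_alarms.append((f, p))
            else:
                live.append(track)
    for j in unassigned:
        live.append(Track(id=next_id, birth_frame=frame, points=[obs.centroids[j]]))
        next_id += 1
    return live, finished, false_alarms, next_id


def _terminate(track: Track) -> Track:
    """Close a track, trimming trailing missing slots."""
    while track.points and track.points[-1] is None:
        track.points.pop()
    track.terminated = True
    track.miss_count = 0
    return track


def run_association(
    all_obs: Sequence[FrameObservations],
    model: Optional[SoftmaxModel],
    params: GatingParams,
    scorer=None,
) -> AssociationResult:
    """Single-scan forward association over a whole observation sequence.

    Deterministic given its inputs.  Tracks alive at the end of the sequence
    are closed; those that never gained a second point become false alarms.
    """
    if len(all_obs) < 2:
        raise ValueError("need at least 2 frames of observations")
    if scorer is None:
        scorer = HDBNScorer(model)
    live: list = []
    finished: list = []
    tau0: list = []
    next_id = 1
    for obs in all_obs:
        assignment, unassigned = assign_frame(live, obs, model, params, scorer=scorer)
        live, done, fas, next_id = step_lifecycle(
            live, assignment, unassigned, obs, obs.frame, params, next_id
        )
        finished.extend(done)
        tau0.extend(fas)
    for track in live:
        track = _terminate(track)
        if track.n_observed() >= 2:
            finished.append(track)
        else:
            f, p = track.first_observed()
            tau0.append((f, p))
    finished.sort(key=lambda t: t.id)
    return AssociationResult(tracks=finished, false_alarms=tau0)


def build_reference_library(dataset: dict, held_out_sequence=None) -> ReferenceLibrary:
    """Normalized exemplar library from ground-truth tracks, with hold-out.

    ``dataset`` maps a sequence identifier to its list of tracks.  All
    tracks not belonging to ``held_out_sequence`` are gap-interpolated,
    polar-converted and normalized.  Tracks with fewer than 2 observed
    points carry no step information and are skipped.
    """
    polar_tracks, sources = [], []
    for seq_id, tracks in dataset.items():
        if seq_id == held_out_sequence:
            continue
        for tr in tracks:
            if tr.n_observed() < 2:
                continue
            polar_tracks.append(normalize_track(to_polar(interpolate_missing(tr))))
            sources.append(seq_id)
    if not polar_tracks:
        raise ValueError("reference library is empty after hold-out")
    return ReferenceLibrary(tracks=polar_tracks, source_sequence_ids=sources)


def validate_result(result: AssociationResult, all_obs: Sequence[FrameObservations]) -> None:
    """Assert the structural track conditions on an association output.

    Checks that every confirmed track has at least two observed points and
    at most one observation per frame, that tracks are pairwise disjoint,
    and that the tracks plus the false-alarm set partition the observation
    set exactly.  Raises ``AssertionError`` on violation.
    """
    pool: dict = {}
    for obs in all_obs:
        for p in obs.centroids:
            key = (obs.frame, round(p.x, 9), round(p.y, 9))
            pool[key] = pool.get(key, 0) + 1
    used: dict = {}

    def _consume(frame: int, p: Point) -> None:
        key = (frame, round(p.x, 9), round(p.y, 9))
        used[key] = used.get(key, 0) + 1

    for tr in result.tracks:
        assert tr.n_observed() >= 2, f"track {tr.id} has < 2 observed points"
        assert tr.points[0] is not None and tr.points[-1] is not None, (
            f"track {tr.id} has untrimmed missing endpoints"
        )
        for frame, p in zip(tr.frames(), tr.points):
            if p is not None:
                _consume(frame, p)
    for frame, p in result.false_alarms:
        _consume(frame, p)
    assert used == pool, "tracks and false alarms do not partition the observations"
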