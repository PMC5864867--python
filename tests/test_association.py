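import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st_

from spermtrack import (
    GatingParams,
    PolarTrack,
    ReferenceLibrary,
    SoftmaxModel,
    Track,
    assign_frame,
    build_reference_library,
    candidate_density,
    candidate_probabilities,
    gate_candidates,
    region_weights,
    run_association,
    validate_result,
)
from spermtrack.association import MISS, CandidateSet, NoReferenceError, step_lifecycle

from conftest import make_obs, make_track


def library_from_steps(step_lists):
    """Reference library from explicit (d, theta) step lists."""
    tracks = [PolarTrack([s[0] for s in sl], [s[1] for s in sl]) for sl in step_lists]
    return ReferenceLibrary(tracks=tracks, source_sequence_ids=list(range(len(tracks))))


class TestGating:
    params = GatingParams(v_bar=8.0, d_bar=5)

    def test_observation_inside_circle(self):
        track = make_track([(5, 10), (10, 10)])
        cands = gate_candidates(track, make_obs(2, [(15, 10)]), self.params)
        assert len(cands) == 1
        j, d, theta = cands.members[0]
        assert j == 0 and d == pytest.approx(5.0) and theta == pytest.approx(0.0)

    def test_radius_grows_with_misses_but_still_excludes(self):
        track = make_track([(5, 10), (10, 10)])
        obs = make_obs(2, [(30, 10)])
        assert len(gate_candidates(track, obs, self.params)) == 0  # 20 > 8
        track.points.append(None)
        track.miss_count = 1
        assert len(gate_candidates(track, obs, self.params)) == 0  # 20 > 16

    def test_empty_observations(self):
        track = make_track([(0, 0), (1, 0)])
        assert len(gate_candidates(track, make_obs(2, []), self.params)) == 0

    def test_candidate_heading_in_normalized_frame(self):
        # Track moving straight up: candidate continuing up is heading 0 in
        # the track's own frame.
        track = make_track([(10, 20), (10, 15)])
        cands = gate_candidates(track, make_obs(2, [(10, 11)]), self.params)
        _, d, theta = cands.members[0]
        assert d == pytest.approx(4.0)
        assert theta == pytest.approx(0.0, abs=1e-12)

    def test_terminated_track_rejected(self):
        track = make_track([(0, 0), (1, 0)])
        track.terminated = True
        with pytest.raises(ValueError):
            gate_candidates(track, make_obs(2, []), self.params)


class TestRegionWeights:
    def test_symmetric_when_all_distances_equal(self):
        growing = PolarTrack([1], [0])
        lib = library_from_steps([[(1, 0)], [(1, 0)], [(1, 0)]])
        np.testing.assert_allclose(region_weights(growing, lib, 1), [1 / 3] * 3)

    def test_closed_form_softmax(self):
        growing = PolarTrack([1], [0])
        ln2 = math.log(2)
        lib = library_from_steps([[(1, 0)], [(1 + ln2, 0)], [(1 + ln2, 0)]])
        np.testing.assert_allclose(
            region_weights(growing, lib, 1), [0.5, 0.25, 0.25], atol=1e-12
        )

    def test_saturation_on_near_region(self):
        growing = PolarTrack([1], [0])
        lib = library_from_steps([[(1, 0)], [(51, 0)], [(51, 0)]])
        w = region_weights(growing, lib, 1)
        assert w[0] == pytest.approx(1.0, abs=1e-20)

    def test_short_library_tracks_get_zero_weight(self):
        growing = PolarTrack([1, 1], [0, 0])
        lib = library_from_steps([[(1, 0)], [(1, 0), (1, 0)]])
        w = region_weights(growing, lib, 2)
        assert w[0] == 0.0 and w[1] == pytest.approx(1.0)

    def test_no_comparable_reference_raises(self):
        growing = PolarTrack([1, 1], [0, 0])
        lib = library_from_steps([[(1, 0)]])
        with pytest.raises(NoReferenceError):
            region_weights(growing, lib, 2)

    @given(st_.integers(0, 10**6), st_.integers(1, 5), st_.integers(2, 8))
    def test_weights_sum_to_one(self, seed, t, n_lib):
        rng = np.random.default_rng(seed)
        growing = PolarTrack(rng.uniform(0, 10, t), rng.uniform(-3, 3, t))
        lib = library_from_steps(
            [
                [
                    (rng.uniform(0, 10), 0.0 if k == 0 else rng.uniform(-3, 3))
                    for k in range(int(rng.integers(t, t + 3)))
                ]
                for _ in range(n_lib)
            ]
        )
        assert abs(region_weights(growing, lib, t).sum() - 1.0) < 1e-9


class TestCandidateDensity:
    def test_value_at_mean(self):
        # Variance λ·d = 2 on both axes: density at the mean is 1/(4π).
        val = candidate_density((4.0, 0.5), (4.0, 0.5), lambda_=0.5)
        assert val == pytest.approx(1.0 / (4 * math.pi))

    def test_zero_step_uses_floor(self):
        val = candidate_density((0.1, 0.0), (0.0, 0.0), lambda_=0.25, sigma_floor=0.25)
        assert np.isfinite(val) and val > 0

    def test_gaussian_tail(self):
        var = 0.25 * 4.0
        sigma = math.sqrt(var)
        at_mean = candidate_density((4.0, 0.0), (4.0, 0.0), lambda_=0.25)
        far = candidate_density((4.0 + 6 * sigma, 0.0), (4.0, 0.0), lambda_=0.25)
        assert far < at_mean * 1e-7

    def test_angular_residual_wraps(self):
        near = candidate_density((1.0, math.pi - 0.01), (1.0, -math.pi + 0.01), lambda_=0.25)
        at_mean = candidate_density((1.0, 0.0), (1.0, 0.0), lambda_=0.25)
        assert near == pytest.approx(at_mean, rel=1e-2)


class TestCandidateProbabilities:
    def test_single_candidate_gets_probability_one(self):
        growing = PolarTrack([1], [0])
        model = SoftmaxModel(library=library_from_steps([[(1, 0), (2, 0.3)]]))
        cands = CandidateSet(1, 1, [(0, 9.0, 2.0)])
        np.testing.assert_allclose(
            candidate_probabilities(cands, growing, model, 1), [1.0]
        )

    def test_equal_densities_split_evenly(self):
        growing = PolarTrack([1], [0])
        model = SoftmaxModel(library=library_from_steps([[(1, 0), (2, 0)]]))
        cands = CandidateSet(1, 1, [(0, 2.5, 0.0), (1, 1.5, 0.0)])
        np.testing.assert_allclose(
            candidate_probabilities(cands, growing, model, 1), [0.5, 0.5]
        )

    def test_mixture_of_region_opinions(self):
        # Two regions with weights (0.75, 0.25); each region puts essentially
        # all its mass on a different candidate -> mixture (0.75, 0.25).
        ln3 = math.log(3)
        lib = library_from_steps(
            [[(1, 0), (2, 0)], [(1 + ln3, 0), (10, 0)]]
        )
        model = SoftmaxModel(library=lib, lambda_=0.01, sigma_floor=0.01)
        growing = PolarTrack([1], [0])
        cands = CandidateSet(1, 1, [(0, 2.0, 0.0), (1, 10.0, 0.0)])
        probs = candidate_probabilities(cands, growing, model, 1)
        np.testing.assert_allclose(probs, [0.75, 0.25], atol=1e-6)

    def test_total_underflow_falls_back_to_uniform(self):
        lib = library_from_steps([[(1, 0), (2, 0)]])
        model = SoftmaxModel(library=lib, lambda_=1e-6, sigma_floor=1e-6)
        growing = PolarTrack([1], [0])
        cands = CandidateSet(1, 1, [(0, 1e200, 3.0), (1, 2e200, -3.0)])
        probs = candidate_probabilities(cands, growing, model, 1)
        np.testing.assert_allclose(probs, [0.5, 0.5])

    @given(st_.integers(0, 10**6), st_.integers(1, 4), st_.integers(1, 5), st_.integers(1, 6))
    def test_probabilities_sum_to_one(self, seed, t, m, n_lib):
        rng = np.random.default_rng(seed)
        growing = PolarTrack(rng.uniform(0, 10, t), rng.uniform(-3, 3, t))
        lib = library_from_steps(
            [
                [
                    (rng.uniform(0, 10), 0.0 if k == 0 else rng.uniform(-3, 3))
                    for k in range(t + 1)
                ]
                for _ in range(n_lib)
            ]
        )
        model = SoftmaxModel(library=lib)
        cands = CandidateSet(
            1, t, [(j, rng.uniform(0, 15), rng.uniform(-3, 3)) for j in range(m)]
        )
        probs = candidate_probabilities(cands, growing, model, t)
        assert abs(probs.sum() - 1.0) < 1e-9
        assert (probs >= 0).all()

    def test_small_lambda_concentrates_on_true_continuation(self):
        # With the true continuation in the library, shrinking λ makes the
        # matching candidate's probability approach 1.
        growing = PolarTrack([3], [0])
        lib = library_from_steps([[(3, 0), (3, 0.2)]])
        cands = CandidateSet(1, 1, [(0, 3.0, 0.2), (1, 4.5, -1.0)])
        last = None
        for lam in (1.0, 0.1, 0.01):
            model = SoftmaxModel(library=lib, lambda_=lam, sigma_floor=lam)
            p = candidate_probabilities(cands, growing, model, 1)[0]
            if last is not None:
                assert p >= last
            last = p
        assert last > 1 - 1e-9


class _StubScorer:
    """Feeds assign_frame a fixed cost table (track id, obs index) -> cost."""

    def __init__(self, table, miss_cost):
        self.table = table
        self.miss_cost = miss_cost

    def costs(self, track, cands, params):
        return (
            np.array([self.table[(track.id, j)] for j, _, _ in cands.members]),
            self.miss_cost,
        )


def brute_force_joint(track_ids, n_obs, table, miss_cost, gated):
    """Best joint assignment by enumerating every track->obs|MISS mapping."""
    best, best_total = None, math.inf
    options = [
        [j for j in range(n_obs) if (tid, j) in gated] + [MISS] for tid in track_ids
    ]
    for combo in itertools.product(*options):
        used = [j for j in combo if j is not MISS]
        if len(used) != len(set(used)):
            continue
        total = sum(
            miss_cost if j is MISS else table[(tid, j)]
            for tid, j in zip(track_ids, combo)
        )
        if total < best_total:
            best_total = total
            best = dict(zip(track_ids, combo))
    return best, best_total


class TestAssignFrame:
    gating = GatingParams(v_bar=100.0, d_bar=5)

    def test_single_track_single_candidate(self):
        track = make_track([(0, 0), (1, 0)], track_id=1)
        obs = make_obs(2, [(2, 0)])
        scorer = _StubScorer({(1, 0): 0.0}, miss_cost=3.0)
        assignment, unassigned = assign_frame([track], obs, None, self.gating, scorer=scorer)
        assert assignment == {1: 0} and unassigned == []

    def test_joint_optimum_beats_greedy(self):
        # Probabilities p(t1->o1)=0.9, p(t1->o2)=0.1, p(t2->o1)=0.8,
        # p(t2->o2)=0.7: the joint product optimum pairs t1-o1, t2-o2.
        t1 = make_track([(0, 0), (0, 1)], track_id=1)
        t2 = make_track([(5, 0), (5, 1)], track_id=2)
        obs = make_obs(2, [(0, 2), (5, 2)])
        table = {
            (1, 0): -math.log(0.9), (1, 1): -math.log(0.1),
            (2, 0): -math.log(0.8), (2, 1): -math.log(0.7),
        }
        scorer = _StubScorer(table, miss_cost=10.0)
        assignment, unassigned = assign_frame([t1, t2], obs, None, self.gating, scorer=scorer)
        assert assignment == {1: 0, 2: 1}
        assert unassigned == []

    def test_empty_candidate_set_yields_miss(self):
        track = make_track([(0, 0), (1, 0)], track_id=1)
        obs = make_obs(2, [(500, 500)])
        gating = GatingParams(v_bar=5.0)
        assignment, unassigned = assign_frame(
            [track], obs, None, gating, scorer=_StubScorer({}, 3.0)
        )
        assert assignment == {1: MISS} and unassigned == [0]

    @given(st_.integers(0, 10**6), st_.integers(1, 4), st_.integers(0, 4))
    def test_matches_brute_force_joint_assignment(self, seed, n_tracks, n_obs):
        rng = np.random.default_rng(seed)
        tracks = [
            make_track([(10 * i, 0), (10 * i, 1)], track_id=i + 1)
            for i in range(n_tracks)
        ]
        obs = make_obs(2, [tuple(rng.uniform(0, 40, 2)) for _ in range(n_obs)])
        gating = GatingParams(v_bar=1000.0, d_bar=5)  # everything gated
        table = {
            (t.id, j): float(rng.uniform(0, 5))
            for t in tracks
            for j in range(n_obs)
        }
        miss_cost = float(rng.uniform(0, 5))
        scorer = _StubScorer(table, miss_cost)
        assignment, _ = assign_frame(tracks, obs, None, gating, scorer=scorer)
        gated = set(table)
        _, best_total = brute_force_joint(
            [t.id for t in tracks], n_obs, table, miss_cost, gated
        )
        total = sum(
            miss_cost if j is MISS else table[(tid, j)]
            for tid, j in assignment.items()
        )
        assert total == pytest.approx(best_total, abs=1e-9)


class TestLifecycle:
    gating = GatingParams(v_bar=8.0, d_bar=5)

    def test_miss_threshold_terminates(self):
        track = make_track([(0, 0), (1, 0), None, None, None, None], track_id=1)
        track.miss_count = 4
        live, finished, fas, _ = step_lifecycle(
            [track], {1: MISS}, [], make_obs(6, []), 6, self.gating, next_id=2
        )
        assert live == [] and len(finished) == 1
        done = finished[0]
        assert done.terminated
        assert done.points[-1] is not None  # trailing misses trimmed

    def test_second_point_confirms_a_tentative_track(self):
        obs3 = make_obs(3, [(10, 10)])
        live, _, _, nid = step_lifecycle([], {}, [0], obs3, 3, self.gating, next_id=1)
        assert len(live) == 1 and live[0].birth_frame == 3
        obs4 = make_obs(4, [(12, 10)])
        live, finished, fas, _ = step_lifecycle(
            live, {1: 0}, [], obs4, 4, self.gating, next_id=nid
        )
        assert live[0].n_observed() == 2

    def test_lone_observation_becomes_false_alarm(self):
        obs = make_obs(0, [(50, 50)])
        live, _, _, nid = step_lifecycle([], {}, [0], obs, 0, self.gating, next_id=1)
        track = live[0]
        fas_all = []
        for t in range(1, 6):
            live, finished, fas, nid = step_lifecycle(
                live, {track.id: MISS}, [], make_obs(t, []), t, self.gating, nid
            )
            fas_all.extend(fas)
        assert live == [] and fas_all == [(0, obs.centroids[0])]


def straight_line_obs(n_frames=10, step=4.0, y=50.0):
    return [make_obs(t, [(10 + step * t, y)]) for t in range(n_frames)]


def simple_model(extra_steps=30):
    lib = library_from_steps([[(4.0, 0.0)] * extra_steps])
    return SoftmaxModel(library=lib)


class TestRunAssociation:
    gating = GatingParams(v_bar=8.0, d_bar=5)

    def test_single_target_exact_recovery(self):
        obs = straight_line_obs()
        result = run_association(obs, simple_model(), self.gating)
        validate_result(result, obs)
        assert result.K == 1 and result.false_alarms == []
        got = [(p.x, p.y) for p in result.tracks[0].points]
        expected = [(o.centroids[0].x, o.centroids[0].y) for o in obs]
        assert got == expected

    def test_two_separated_targets_no_swap(self):
        obs = [make_obs(t, [(10 + 4 * t, 50), (10 + 4 * t, 400)]) for t in range(10)]
        result = run_association(obs, simple_model(), self.gating)
        validate_result(result, obs)
        assert result.K == 2
        ys = sorted({p.y for tr in result.tracks for p in tr.points if p})
        assert ys == [50.0, 400.0]
        for tr in result.tracks:
            assert len({p.y for p in tr.points if p}) == 1

    def test_pure_clutter_yields_no_tracks(self):
        # Every pair of observations within a d̄-frame window is farther
        # apart than the largest possible gate radius (5 × 8 = 40 px).
        obs = [make_obs(t, [(100.0 * t, 50.0 * t)]) for t in range(6)]
        result = run_association(obs, simple_model(), self.gating)
        validate_result(result, obs)
        assert result.K == 0
        assert len(result.false_alarms) == 6

    def test_gap_recovery_after_missed_detection(self):
        obs = straight_line_obs(10)
        obs[4] = make_obs(4, [])  # one dropped frame
        result = run_association(obs, simple_model(), self.gating)
        validate_result(result, obs)
        assert result.K == 1
        assert result.tracks[0].points[4] is None

    def test_deterministic(self):
        obs = [make_obs(t, [(10 + 4 * t, 50), (400 - 3 * t, 300)]) for t in range(8)]
        r1 = run_association(obs, simple_model(), self.gating)
        r2 = run_association(obs, simple_model(), self.gating)
        assert [(t.id, [(p.x, p.y) if p else None for p in t.points]) for t in r1.tracks] == [
            (t.id, [(p.x, p.y) if p else None for p in t.points]) for t in r2.tracks
        ]


class TestBuildReferenceLibrary:
    def _dataset(self):
        return {
            s: [
                make_track([(0, 0), (i + 1, 0), (2 * (i + 1), i)], track_id=i)
                for i in range(2)
            ]
            for s in ("a", "b", "c")
        }

    def test_hold_one_out(self):
        lib = build_reference_library(self._dataset(), held_out_sequence="b")
        assert len(lib) == 4
        assert "b" not in lib.source_sequence_ids

    def test_hold_nothing_out(self):
        lib = build_reference_library(self._dataset())
        assert len(lib) == 6

    def test_empty_library_rejected(self):
        data = {"a": self._dataset()["a"]}
        with pytest.raises(ValueError):
            build_reference_library(data, held_out_sequence="a")

    def test_library_tracks_are_normalized(self):
        lib = build_reference_library(self._dataset())
        for pt in lib.tracks:
            assert pt.theta[0] == pytest.approx(0.0, abs=1e-12)
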