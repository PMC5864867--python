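import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

from spermtrack import FrameObservations, Point, Track

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_track(coords, track_id=1, birth_frame=0):
    """Track from a list of (x, y) tuples or None for missing slots."""
    pts = [None if c is None else Point(*c) for c in coords]
    return Track(id=track_id, birth_frame=birth_frame, points=pts)


def make_obs(frame, coords):
    return FrameObservations(frame=frame, centroids=[Point(*c) for c in coords])


def brute_force_assignment(cost):
    """Minimum-cost partial assignment by exhaustive enumeration.

    Considers every injective mapping of rows to columns restricted to
    finite-cost pairs; returns (best mapping, best total cost).
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    best, best_total = {}, math.inf
    k_max = min(n, m)
    # The empty assignment has total 0 only if we must use max matchings;
    # the Hungarian solution always uses a maximum matching over finite
    # pairs, so enumerate only assignments of maximal size first.
    for k in range(k_max, -1, -1):
        found = False
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                total = 0.0
                ok = True
                for r, c in zip(rows, cols):
                    if not np.isfinite(cost[r, c]) or cost[r, c] >= 1e8:
                        ok = False
                        break
                    total += cost[r, c]
                if ok:
                    found = True
                    if total < best_total:
                        best_total = total
                        best = dict(zip(rows, cols))
        if found:
            return best, best_total
    return {}, 0.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
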