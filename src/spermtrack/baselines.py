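"""Nearest Neighbour Filter baseline.

A heuristic tracker that assigns each new observation to the closest
predicted position, where the prediction is simply the track's last
assigned point.  It shares the observation model, gating, joint Hungarian
assignment, and the full track lifecycle (births, miss counter, termination
at d̄, false-alarm routing) with the probabilistic tracker, so any
performance difference between the two isolates the association cost alone.
"""

from __future__ import annotations

from typing import Sequence

from .association import AssociationResult, GatingParams, NNFScorer, run_association
from .segmentation import FrameObservations

__all__ = ["nnf_associate"]


def nnf_associate(
    all_obs: Sequence[FrameObservations],
    params: GatingParams,
) -> AssociationResult:
    """Global-nearest-neighbour association over an observation sequence.

    Per frame, the cost of pairing a live track with a gated observation is
    the Euclidean distance from the track's last point; the joint assignment
    is solved optimally so no observation is used twice (global rather than
    greedy per-track nearest neighbour).
    """
    return run_association(all_obs, model=None, params=params, scorer=NNFScorer())
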