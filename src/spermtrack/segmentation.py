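"""Per-frame detection of spermatozoa heads and detection-level scoring.

In negative phase-contrast, sperm heads appear as small bright ellipses on a
darker, noisy background, surrounded by a halo ring.  Detection is a
four-step pipeline per frame:

1. adaptive binarization against local first-order statistics (a pixel is
   foreground when it exceeds the local mean by ``sensitivity`` local
   standard deviations);
2. morphological closing with a circular structuring element of radius
   ``r_SE`` to re-connect fragmented large components;
3. hole filling;
4. connected-component labeling (8-connectivity) and an area band filter —
   only blobs with area in ``[beta_min, beta_max]`` pixels survive.

The centroids of surviving blobs form the frame's observation set.  Sweeping
``beta_max`` trades detection probability against false-alarm rate and is
the knob used to prepare observation sets of graded quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .geometry import Point, solve_assignment

__all__ = [
    "SegmentationParams",
    "FrameObservations",
    "DetectionScore",
    "segment_frame",
    "match_detections",
    "sequence_detection_stats",
]

#: Matching radius (pixels) for pairing detections with ground truth: the
#: major-axis length of a normal sperm head (4.3 µm at 0.833 µm/px).
MATCH_RADIUS_PX = 5.0


@dataclass
class SegmentationParams:
    """Knobs of the head-detection pipeline.

    ``window`` and ``sensitivity`` control the local-statistics threshold;
    ``r_SE`` the closing element radius; ``beta_min``/``beta_max`` the blob
    area band in pixels.
    """

    window: int = 31
    sensitivity: float = 4.0
    r_SE: int = 5
    beta_min: int = 1
    beta_max: int = 25

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.r_SE < 1:
            raise ValueError("r_SE must be >= 1")
        if not (1 <= self.beta_min <= self.beta_max):
            raise ValueError("need 1 <= beta_min <= beta_max")


@dataclass
class FrameObservations:
    """Detected head centroids for one frame."""

    frame: int
    centroids: list = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.centroids)

    def as_array(self) -> np.ndarray:
        if not self.centroids:
            return np.empty((0, 2))
        return np.array([[p.x, p.y] for p in self.centroids], dtype=float)


@dataclass
class DetectionScore:
    """Detection quality of one frame against ground truth.

    ``p_d_t`` is true positives over ground-truth count; it is ``None`` when
    the frame has no ground-truth points (undefined ratio, excluded from
    averages).  ``far_t`` counts detections left unmatched.
    """

    n_TP: int
    p_d_t: Optional[float]
    far_t: int
    missed: int


def segment_frame(image: np.ndarray, params: Optional[SegmentationParams] = None) -> "FrameObservations | np.ndarray":
    """Detect head centroids in one grayscale frame.

    Returns a :class:`FrameObservations` with ``frame=0``; callers tracking
    a sequence overwrite the frame index.
    """
    params = params or SegmentationParams()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    img = img.astype(float)

    # Local first-order statistics: mean and standard deviation in a
    # window × window neighbourhood (uniform filter; reflective borders).
    w = params.window
    mu = ndimage.uniform_filter(img, size=w, mode="reflect")
    mu2 = ndimage.uniform_filter(img * img, size=w, mode="reflect")
    var = np.maximum(mu2 - mu * mu, 0.0)
    mask = img > mu + params.sensitivity * np.sqrt(var)

    mask = closing(mask, disk(params.r_SE))
    mask = ndimage.binary_fill_holes(mask)

    labels = label(mask, connectivity=2)  # 8-connectivity
    centroids = []
    for region in regionprops(labels):
        if params.beta_min <= region.area <= params.beta_max:
            cy, cx = region.centroid
            centroids.append(Point(float(cx), float(cy)))
    return FrameObservations(frame=0, centroids=centroids)


def match_detections(
    obs: FrameObservations,
    truth: FrameObservations,
    radius: float = MATCH_RADIUS_PX,
) -> DetectionScore:
    """Score a frame's detections against ground-truth positions.

    Detections and truth points are paired by minimum-total-distance
    assignment; pairs farther apart than ``radius`` are forbidden.  Matched
    pairs are true positives; unmatched detections are false alarms.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    a = obs.as_array()
    b = truth.as_array()
    n_tp = 0
    if len(a) and len(b):
        dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        cost = np.where(dist <= radius, dist, np.inf)
        n_tp = len(solve_assignment(cost))
    m_t = len(b)
    p_d_t = n_tp / m_t if m_t > 0 else None
    return DetectionScore(
        n_TP=n_tp,
        p_d_t=p_d_t,
        far_t=len(a) - n_tp,
        missed=m_t - n_tp,
    )


def sequence_detection_stats(per_frame: Sequence[DetectionScore]) -> tuple[float, float]:
    """Sequence-level mean detection probability and mean false-alarm rate.

    The detection probability is the unweighted mean of the per-frame ratios
    over frames where it is defined; FAR averages over all frames.  The
    dataset-level figure is in turn the unweighted mean of sequence means.
    """
    if not per_frame:
        raise ValueError("need at least one scored frame")
    pds = [s.p_d_t for s in per_frame if s.p_d_t is not None]
    p_bar = float(np.mean(pds)) if pds else float("nan")
    far = float(np.mean([s.far_t for s in per_frame]))
    return p_bar, far
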