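"""Track simulated spermatozoa with the exemplar-library tracker.

Builds a noisy detection-level scene (80% detection probability, two
clutter points per frame, half-pixel jitter), associates the detections
with both the Softmax-CPD tracker and the nearest-neighbour baseline, and
scores each against the known ground truth.  F1 close to 1 means nearly
every true cell was recovered as exactly one track; RMSE is the mean
point-wise error of the recovered paths in pixels.
"""

import spermtrack as sp

# Ground truth for the scene being tracked, and a second, independent
# population whose tracks serve as the exemplar library (never the scene
# under test -- the hold-out rule).
truth = sp.simulate_tracks(sp.MotionParams(n_cells=15, seed=1))
exemplars = sp.simulate_tracks(sp.MotionParams(n_cells=15, seed=2))

obs = sp.corrupt_detections(
    truth, sp.CorruptionParams(p_d=0.8, far_rate=2.0, jitter_sd=0.5, seed=3)
)

v_bar = 1.25 * sp.max_step_displacement(truth + exemplars)
gating = sp.GatingParams(v_bar=v_bar, d_bar=5)
model = sp.SoftmaxModel(library=sp.build_reference_library({"lib": exemplars}))

for name, result in [
    ("hdbn", sp.run_association(obs, model, gating)),
    ("nnf", sp.nnf_associate(obs, gating)),
]:
    sp.validate_result(result, obs)
    m = sp.score_association(result, truth)
    print(
        f"{name:>4}: {result.K} tracks, {len(result.false_alarms)} false alarms | "
        f"P={m.precision:.3f} R={m.recall:.3f} F1={m.f1:.3f} RMSE={m.mean_rmse:.2f} px"
    )
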