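"""Generate a synthetic multimodal head phantom with known ground truth.

Builds one 'animal': an MRI-like template (ellipsoidal brain in a skull
shell with internal structures), post-operative MRI and CT volumes with
a 0.2 mm electrode along a perturbed trajectory, bregma/lambda
landmarks, a target-region labelmap, and the true transforms and
trajectory the pipeline is supposed to recover.
"""

import numpy as np

import stereotrack as st

spec = st.PhantomSpec(
    angle_offset=(1.5, -2.0),   # true deviation from the plan (deg)
    entry_offset=(0.3, -0.2),   # true entry offset (mm, ML/AP)
    seed=7,
)
bundle = st.generate_phantom(spec)

truth = bundle.truth
plan = truth.plan
print(f"grid {spec.shape} at {spec.voxel_size} mm, "
      f"modalities: {sorted(bundle.modalities)}")
ap, ml, depth = plan.target_stereo
print(f"planned target (AP, ML, depth): ({ap}, {ml}, {depth}) mm, "
      f"alpha={plan.alpha} deg -> D_plan = {plan.d_plan:.3f} mm")
print(f"true trajectory: alpha={truth.trajectory.alpha:.2f} deg, "
      f"beta={truth.trajectory.beta:.2f} deg, "
      f"tip at {np.round(truth.trajectory.tip, 3)} mm (template space)")
print(f"true tip inside target region: {truth.in_target}")
# D_plan exceeds the planned depth only for inclined trajectories; the
# true tip sits at exactly D_plan along the perturbed axis from the dura.
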