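"""Recover a known inter-image misalignment by MI registration.

A post-operative MRI is generated with a known rigid pose offset from
the template (scanner repositioning); mutual-information registration
estimates the transform back to template space, and the residual versus
the recorded truth quantifies registration accuracy.
"""

import numpy as np

import stereotrack as st

spec = st.PhantomSpec(
    shape=(56, 72, 48), voxel_size=0.25,   # coarse grid: registration only
    noise_sd_mri=0.0, noise_sd_ct=0.0,
    modalities=("MRIpost",),
    misalignments={"MRIpost": (3.0, -2.0, 4.0, 1.2, -0.8, 0.5)},
)
bundle = st.generate_phantom(spec)

estimated = st.register_mi(bundle.modalities["MRIpost"], bundle.template,
                           dof="rigid6")
truth = bundle.truth.transforms["MRIpost"]

residual = np.linalg.inv(truth.matrix) @ estimated.matrix
angle = np.degrees(np.arccos(np.clip((np.trace(residual[:3, :3]) - 1) / 2,
                                     -1, 1)))
shift = np.linalg.norm(residual[:3, 3])
print(f"true misalignment: rotations (3, -2, 4) deg, "
      f"translation (1.2, -0.8, 0.5) mm")
print(f"registration residual: {angle:.3f} deg rotation, "
      f"{shift:.3f} mm translation at the head center")
# residuals of a few hundredths of a mm/deg mean electrode coordinates
# transfer to template space with sub-voxel accuracy
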