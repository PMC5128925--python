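import numpy as np
import pytest

import stereotrack as st


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """Default-resolution zero-noise phantom in template space with a
    slightly perturbed true trajectory (shared across modules)."""
    spec = st.PhantomSpec(
        noise_sd_mri=0.0, noise_sd_ct=0.0,
        modalities=("MRIpost", "CTpost"),
        misalignments={"MRIpost": (0.0,) * 6, "CTpost": (0.0,) * 6},
        angle_offset=(1.5, -2.0), entry_offset=(0.3, -0.2),
    )
    return st.generate_phantom(spec)


@pytest.fixture(scope="session")
def registration_spec():
    """Coarse phantom spec for registration tests (no segmentation —
    the 0.2 mm electrode is sub-voxel at this resolution)."""
    def make(misalignment, noise=0.0, seed=0):
        return st.PhantomSpec(
            shape=(56, 72, 48), voxel_size=0.25,
            noise_sd_mri=noise, noise_sd_ct=0.0,
            modalities=("MRIpost",),
            misalignments={"MRIpost": tuple(misalignment)},
            seed=seed,
        )
    return make


def transform_errors(estimated, truth, center=np.zeros(3)):
    """(rotation deg, displacement at ``center`` mm) of the residual map."""
    E = np.linalg.inv(truth.matrix) @ estimated.matrix
    ang = np.degrees(np.arccos(np.clip((np.trace(E[:3, :3]) - 1) / 2, -1, 1)))
    disp = np.linalg.norm(E[:3, :3] @ center + E[:3, 3] - center)
    return float(ang), float(disp)
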