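import numpy as np
import pytest

from eptplan.phantoms import (BrainStackSpec, PhantomSpec,
                              generate_abdomen_phantom,
                              generate_brain_stack_phantom,
                              generate_tube_phantom)


@pytest.fixture(scope="session")
def abdomen_ct():
    """Default noiseless CT abdomen phantom (volume, truth)."""
    return generate_abdomen_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def abdomen_ct_noisy():
    # noise sd = 10% of the liver-background contrast (60 - (-1000)) = 106
    return generate_abdomen_phantom(PhantomSpec(noise_sd=106.0, seed=7))


@pytest.fixture(scope="session")
def abdomen_mri():
    return generate_abdomen_phantom(PhantomSpec(modality="MRI"))


@pytest.fixture(scope="session")
def abdomen_mri_noisy():
    # 10% of the MRI liver-background contrast (400 - 20) = 38
    return generate_abdomen_phantom(PhantomSpec(modality="MRI", noise_sd=38.0, seed=7))


@pytest.fixture(scope="session")
def brain_stack():
    return generate_brain_stack_phantom(BrainStackSpec())


@pytest.fixture(scope="session")
def tube():
    return generate_tube_phantom()


@pytest.fixture(scope="session")
def small_abdomen_spec():
    """A small, fast phantom for I/O and pipeline tests."""
    return PhantomSpec(shape=(32, 32, 12), spacing=(2.0, 2.0, 4.0),
                       liver_semiaxes=(24.0, 20.0, 16.0), tumor_radius=6.0,
                       vessel_radius=3.0, include_bone=False,
                       tumor_center=(38.0, 32.0, 24.0))


@pytest.fixture(scope="session")
def liver_seed_voxel(abdomen_mri):
    """Deepest liver-parenchyma voxel (away from vessel/tumor)."""
    from scipy import ndimage

    _, truth = abdomen_mri
    d = ndimage.distance_transform_edt(truth.labels == 1)
    return tuple(int(v) for v in np.unravel_index(np.argmax(d), d.shape))
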