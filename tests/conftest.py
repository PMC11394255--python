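import numpy as np
import pytest

from dermibc import LesionSpec, generate_lesion_image, radial_profile, segment_lesion
from dermibc.reference import published_reader_table, reconstruct_response_table


@pytest.fixture(scope="session")
def modulated_lesion():
    """Default lesion with A = 0.2, phi = 0 plus its full analysis chain."""
    spec = LesionSpec(angular_modulation=(0.2, 0.0))
    image, truth = generate_lesion_image(spec)
    mask = segment_lesion(image)
    profile = radial_profile(image, mask)
    return {"spec": spec, "image": image, "truth": truth, "mask": mask, "profile": profile}


@pytest.fixture(scope="session")
def uniform_lesion():
    """Unmodulated lesion (A = 0): the angular profile must be flat."""
    spec = LesionSpec()
    image, truth = generate_lesion_image(spec)
    mask = segment_lesion(image)
    return {"spec": spec, "image": image, "truth": truth, "mask": mask}


@pytest.fixture(scope="session")
def published():
    return published_reader_table(include_mean=True)


@pytest.fixture(scope="session")
def reconstructed_table():
    return reconstruct_response_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
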