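import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import faceval as fv


def random_rigid(rng) -> fv.RigidTransform:
    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1))).as_matrix()
    return fv.RigidTransform(rot, rng.uniform(-50, 50, 3))


@pytest.fixture(scope="session")
def face_pair():
    """Reference synthetic face and landmarks at moderate resolution."""
    spec = fv.SyntheticFaceSpec(resolution=61)
    mesh, lms = fv.generate_face(spec)
    return spec, mesh, lms


@pytest.fixture(scope="session")
def small_face():
    """Coarse face for speed-sensitive registration tests."""
    spec = fv.SyntheticFaceSpec(resolution=41)
    mesh, lms = fv.generate_face(spec)
    return spec, mesh, lms


@pytest.fixture
def toy_lms():
    """Hand-placed landmark set with plausible anthropometric magnitudes."""
    return fv.LandmarkSet({
        "Sn": [0.0, 85.0, -15.0],
        "Sto": [0.0, 83.0, -36.8],
        "Sl": [0.0, 80.0, -48.0],
        "Ls": [0.0, 86.0, -28.0],
        "Li": [0.0, 84.0, -44.0],
        "Lch": [22.0, 75.0, -37.0],
        "Rch": [-22.0, 75.0, -37.0],
        "CphL": [5.0, 85.0, -26.0],
        "CphR": [-5.0, 85.0, -26.0],
        "Gl": [0.0, 78.0, 42.0],
        "N'": [0.0, 75.0, 33.0],
        "Prn": [0.0, 95.0, 0.0],
        "Pg'": [0.0, 82.0, -60.0],
        "Gn'": [0.0, 78.0, -68.0],
    })
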