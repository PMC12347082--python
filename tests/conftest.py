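import numpy as np
import pytest

from orthoplan.geometry import RigidTransform, compose_clinical_rotation
from orthoplan.simulate import template_anatomy, template_landmarks


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture(scope="session")
def template():
    landmarks, meshes = template_anatomy()
    return landmarks, meshes


@pytest.fixture
def t0_landmarks():
    return template_landmarks(patient_id="pt", timepoint="T0")


def random_rigid(rng, max_angle=60.0, max_shift=10.0) -> RigidTransform:
    """Random proper rigid transform with bounded angles/shift."""
    angles = rng.uniform(-max_angle, max_angle, size=3)
    rot = compose_clinical_rotation(*angles)
    return RigidTransform(rot, rng.uniform(-max_shift, max_shift, size=3))
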