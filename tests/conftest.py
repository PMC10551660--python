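import numpy as np
import pytest

from posturekit.grading import default_rubric
from posturekit.synth import FigurineSpec, make_figurine


@pytest.fixture(scope="session")
def rubric():
    return default_rubric()


@pytest.fixture
def null_figurine():
    """Figurine with every deviation zero."""
    return make_figurine(FigurineSpec())


@pytest.fixture
def deviated_spec():
    """One nonzero deviation per index, at distinct values."""
    return FigurineSpec(
        shoulder_tilt_deg=3.7,
        pelvic_obliquity_deg=2.2,
        knee_alignment_deg=-2.0,
        head_forward_cm=3.0,
        pelvic_tilt_deg=18.0,
        scoliosis_deg=2.5,
        scapula_tilt_deg=7.0,
        seed=11,
    )


@pytest.fixture
def deviated_figurine(deviated_spec):
    return make_figurine(deviated_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
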