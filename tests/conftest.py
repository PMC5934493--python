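"""Shared fixtures: models and synthetic subjects reused across tests."""

import numpy as np
import pytest

from exokin import (
    ScaleFactors,
    build_exo_model,
    build_generic_human,
)
from exokin.pipeline import process_subject
from exokin.synthetic_gait import (
    GaitProfileParams,
    generate_subject,
    soft_tissue_preset,
)


@pytest.fixture(scope="session")
def human_model():
    return build_generic_human()


@pytest.fixture(scope="session")
def exo_model():
    return build_exo_model()


@pytest.fixture(scope="session")
def identity_subject():
    """Zero soft tissue, noiseless markers, known scale: a fully
    self-consistent world in which every estimator should be exact."""
    return generate_subject(
        seed=7,
        scale_factors=ScaleFactors(femur=1.0, tibia=1.0, foot=1.0),
        gait=GaitProfileParams(duration=2.0),
        soft=soft_tissue_preset("none"),
    )


@pytest.fixture(scope="session")
def identity_result(identity_subject):
    s = identity_subject
    return process_subject(s.static_no_exo, s.static_with_exo, s.walk_markers)


@pytest.fixture(scope="session")
def misaligned_subject():
    """Short paper-like trial used by solver behavior tests."""
    return generate_subject(
        seed=11,
        gait=GaitProfileParams(duration=2.0),
        soft=soft_tissue_preset("paper-like", seed=11),
    )


@pytest.fixture(scope="session")
def misaligned_result(misaligned_subject):
    s = misaligned_subject
    return process_subject(s.static_no_exo, s.static_with_exo, s.walk_markers)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
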