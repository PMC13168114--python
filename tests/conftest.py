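import numpy as np
import pytest

from mdopac import (
    SkeletonSpec,
    Thresholds,
    generate_capture,
    generate_cohort,
    preset_paper_cohort,
)
from mdopac.geometry import ComponentID


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def ideal_capture():
    return generate_capture(SkeletonSpec.ideal())


@pytest.fixture(scope="session")
def mixed_spec():
    return SkeletonSpec(
        subject_id="mixed",
        angles={
            ComponentID.HIP_LEVEL: 3.0,
            ComponentID.TRUNK_FB: 30.0,
            ComponentID.TRUNK_SS: 12.0,
            ComponentID.NECK_FRONT: 25.0,
            ComponentID.NECK_SIDE: 18.0,
            ComponentID.SHOULDER_RELAXED: 10.0,
            ComponentID.SHOULDER_LEVEL: 2.0,
            ComponentID.UPPER_ARM: 25.0,
            ComponentID.ELBOW: 40.0,
            ComponentID.WRIST: 15.1,
        },
    )


@pytest.fixture(scope="session")
def paper_cohort_with_occlusion():
    """82 generated subjects of which 7 carry occluded upper-arm landmarks."""
    return generate_cohort(preset_paper_cohort(seed=11, n_occluded=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
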