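import numpy as np
import pytest

from earmotion import (
    DirectionGrid,
    EarArrayGeometry,
    EarMotion,
    SamplingSpec,
)

ALL_PATTERN_TOKENS = ["0", "CONST~", "SIN", "SIN~", "COS", "COS~"]


@pytest.fixture(scope="session")
def geometry():
    return EarArrayGeometry()


@pytest.fixture(scope="session")
def sampling():
    return SamplingSpec()


@pytest.fixture(scope="session")
def grid():
    return DirectionGrid.default()


@pytest.fixture(scope="session")
def all_216_motions():
    from earmotion.taxonomy import enumerate_motions

    return enumerate_motions()


@pytest.fixture(scope="session")
def showcase_motions():
    pats = ("0,CONST~,CONST~", "0,COS~,CONST~", "SIN~,COS~,CONST~", "SIN,COS~,SIN~")
    return [EarMotion.from_pattern(p) for p in pats]


def random_unit_directions(rng, n):
    """Uniform directions within the ±60 degree square (as angle pairs)."""
    ang = rng.uniform(-60, 60, (n, 2))
    from earmotion.kinematics import direction_vector

    return ang, direction_vector(ang[:, 0], ang[:, 1])
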