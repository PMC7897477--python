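"""Shared fixtures: expensive synthetic builds are session-scoped so each
geometry is solved once and reused across test modules."""

import numpy as np
import pytest

from g4geom.synth import BuildSpec, build_g4, build_tetrad


LEFT_TWIST = -27.0   # left-handed per-step base rotation magnitude
RIGHT_TWIST = 30.0


@pytest.fixture(scope="session")
def left_twin():
    """Left-handed single-block unimolecular core, no bulges (reference)."""
    return build_g4(BuildSpec(n_tetrads=2, loop_lengths=(1, 1, 1),
                              twist_per_step=LEFT_TWIST))


@pytest.fixture(scope="session")
def left_bulged():
    """Same geometry with one thymine bulge in column 1 (step torsions
    offset by +90° in α and +70° in β relative to the twin)."""
    return build_g4(BuildSpec(n_tetrads=2, loop_lengths=(1, 1, 1),
                              twist_per_step=LEFT_TWIST, bulges=((1, 0),)))


@pytest.fixture(scope="session")
def left_two_bulged():
    return build_g4(BuildSpec(n_tetrads=2, loop_lengths=(1, 1, 1),
                              twist_per_step=LEFT_TWIST,
                              bulges=((1, 0), (2, 0))))


@pytest.fixture(scope="session")
def right_core():
    """Right-handed single-block core, no bulges."""
    return build_g4(BuildSpec(n_tetrads=2, loop_lengths=(1, 1, 1),
                              twist_per_step=RIGHT_TWIST))


@pytest.fixture(scope="session")
def two_block():
    """Four layers in two polarity-inverted blocks joined by a linker."""
    return build_g4(BuildSpec(n_tetrads=4, blocks=(2, 2),
                              loop_lengths=(1, 1, 1),
                              twist_per_step=LEFT_TWIST))


@pytest.fixture(scope="session")
def four_layer_tetramolecular():
    """Four stacked tetrads, four separate strands (no loops)."""
    return build_g4(BuildSpec(n_tetrads=4, loop_lengths=None,
                              twist_per_step=LEFT_TWIST))


@pytest.fixture(scope="session")
def single_tetrad():
    return build_tetrad()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
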