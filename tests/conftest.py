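import numpy as np
import pytest

from mrellg import SymmetryOps, UnitCell, generate_reflections


@pytest.fixture(scope="session")
def cubic_cell():
    return UnitCell(30.0, 30.0, 30.0)


@pytest.fixture(scope="session")
def p1_ops():
    return SymmetryOps.p1()


@pytest.fixture(scope="session")
def p1_reflections(cubic_cell, p1_ops):
    """A medium P1 reflection set shared by likelihood/sigmaa tests."""
    return generate_reflections(cubic_cell, p1_ops, 3.0)


@pytest.fixture(scope="session")
def twofold_ops():
    """Twofold along b: x' = (-x, y, -z)."""
    rots = np.stack([np.eye(3, dtype=int), np.diag([-1, 1, -1])])
    return SymmetryOps(rots, np.zeros((2, 3)))


def random_cell(rng):
    a, b, c = rng.uniform(8.0, 25.0, size=3)
    alpha, beta, gamma = rng.uniform(70.0, 110.0, size=3)
    return UnitCell(a, b, c, alpha, beta, gamma)
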