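import numpy as np
import pytest

import bipbe as bp


@pytest.fixture(scope="session")
def benchmark_spec() -> bp.InitialConditionSpec:
    """The standard gamma-product initial condition (N0=1, p=1, m=0.04)."""
    return bp.InitialConditionSpec()


@pytest.fixture(scope="session")
def toy_axis() -> bp.Grid1D:
    """Doubling grid [0,1,2,4,8] with pivots [0.5, 1.5, 3, 6]."""
    return bp.build_geometric_grid(1.0, 8.0, 4)


@pytest.fixture(scope="session")
def toy_grid(toy_axis) -> bp.Grid2D:
    return bp.Grid2D(toy_axis, toy_axis)


@pytest.fixture(scope="session")
def bench_grid_constant() -> bp.Grid2D:
    """The 20x20 geometric benchmark grid on [0, 21]^2."""
    axis = bp.build_geometric_grid(6e-5, 21.0, 20)
    return bp.Grid2D(axis, axis)


@pytest.fixture(scope="session")
def bench_grid_sum() -> bp.Grid2D:
    """The 20x20 geometric benchmark grid on [0, 30]^2."""
    axis = bp.build_geometric_grid(6e-5, 30.0, 20)
    return bp.Grid2D(axis, axis)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20201127)
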