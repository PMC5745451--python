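import numpy as np
import pytest

from boolstab.infer import BooleanFunction
from boolstab.network import BooleanNetwork
from boolstab.synthetic import SyntheticStudySpec, generate_study


@pytest.fixture
def and_not_net() -> BooleanNetwork:
    """x1' = x1 & x2, x2' = !x1."""
    return BooleanNetwork(
        ("x1", "x2"),
        (BooleanFunction((0, 1), (0, 0, 0, 1)), BooleanFunction((0,), (1, 0))),
    )


@pytest.fixture
def swap_net() -> BooleanNetwork:
    """x1' = x2, x2' = x1."""
    return BooleanNetwork(
        ("x1", "x2"),
        (BooleanFunction((1,), (0, 1)), BooleanFunction((0,), (0, 1))),
    )


def identity_network(n: int) -> BooleanNetwork:
    return BooleanNetwork(
        tuple(f"x{i}" for i in range(n)),
        tuple(BooleanFunction((i,), (0, 1)) for i in range(n)),
    )


def constant_network(n: int, value: int = 0) -> BooleanNetwork:
    return BooleanNetwork(
        tuple(f"x{i}" for i in range(n)),
        tuple(BooleanFunction((), (value,)) for _ in range(n)),
    )


@pytest.fixture(scope="session")
def small_study():
    """Small two-group study: 12 genes, 6 binarizable, noise-free."""
    return generate_study(SyntheticStudySpec(n_genes=12, n_binarizable=6, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
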