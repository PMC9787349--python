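import numpy as np
import pytest
import scipy.sparse as sp

from stringcq import (
    BlockConstraint,
    FeasibilityProblem,
    build_problem,
    scaled_default,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def toy_convex_problem():
    """Consistent 6-row / 3-unknown upper-bound system with a known
    strictly feasible point."""
    gen = np.random.default_rng(7)
    A = gen.normal(size=(6, 3))
    feasible = gen.uniform(0.5, 1.5, size=3)
    b = A @ feasible + gen.uniform(0.2, 0.5, size=6)
    block = BlockConstraint(A=A, bound=b, sense="upper", name="toy")
    return FeasibilityProblem(blocks=[block], nonneg=False), feasible


@pytest.fixture
def two_block_problem():
    """Two coupled dense blocks (one upper with a PVC, one lower) used
    for composition and equivalence checks."""
    gen = np.random.default_rng(11)
    A1 = np.abs(gen.normal(size=(4, 3)))
    A2 = np.abs(gen.normal(size=(3, 3)))
    b1 = np.full(4, 2.0)
    c2 = np.full(3, 1.0)
    blocks = [
        BlockConstraint(A=A1, bound=b1, sense="upper", alpha=0.25, beta=0.5, name="up"),
        BlockConstraint(A=A2, bound=c2, sense="lower", name="low"),
    ]
    return FeasibilityProblem(blocks=blocks, nonneg=True)


@pytest.fixture(scope="session")
def scaled_phantom():
    """The proportionally scaled-down phantom (128 grid, 289 kernels)
    with the packaged prescription; shared across tests for speed."""
    spec, rx = scaled_default()
    problem, dim = build_problem(spec, rx)
    return spec, rx, problem, dim
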