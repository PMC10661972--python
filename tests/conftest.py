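import numpy as np
import pytest

from reglink import ExpressionMatrix, PriorNetwork, make_fixture


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 cells with simple values."""
    values = np.array([
        [0.0, 1.0, 2.0, 3.0],
        [5.0, 4.0, 3.0, 2.0],
        [1.0, 1.0, 1.0, 1.0],
    ])
    return ExpressionMatrix(("G1", "G2", "G3"), ("C1", "C2", "C3", "C4"), values)


@pytest.fixture
def tiny_net() -> PriorNetwork:
    return PriorNetwork(
        genes=("A", "B", "C", "D"),
        edges=frozenset({("A", "B"), ("A", "C"), ("B", "D")}),
        tf_set=frozenset({"A", "B"}),
    )


@pytest.fixture(scope="session")
def smoke_data():
    """The pinned smoke preset: 10 TFs / 50 genes / 100 cells, density 0.05."""
    x, net, _ = make_fixture("smoke")
    return x, net


@pytest.fixture(scope="session")
def strong_signal_data():
    x, net, _ = make_fixture("strong_signal")
    return x, net
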