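import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from gepqsar import DescriptorTable, arithmetic_set  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def abcd_set():
    return arithmetic_set(["a", "b", "c", "d"])


@pytest.fixture
def toy_table():
    """Small labeled table whose positives satisfy x1 + x2 > 0."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 3))
    y = ((X[:, 0] + X[:, 1]) > 0).astype(int)
    frame = pd.DataFrame(X, columns=["x1", "x2", "x3"])
    return DescriptorTable(np.arange(1, 41), frame, y)


def karva_oracle_decode(chromosome):
    """Independent Karva oracle: cumulative-arity index arithmetic.

    The children of the j-th node in decode order occupy the slots starting
    at 1 + sum(arity of nodes 0..j-1).  Built recursively, with no queue,
    so it shares no mechanism with the breadth-first implementation.
    """
    fset = chromosome.function_set
    toks = chromosome.symbols
    arities = []
    # first pass: walk decode order to find each node's token and arity
    n_nodes = 1
    j = 0
    while j < n_nodes:
        sym = fset.lookup(toks[j])
        a = 0 if sym is None else sym.arity
        arities.append(a)
        n_nodes += a
        j += 1

    starts = [1]
    for a in arities[:-1]:
        starts.append(starts[-1] + a)

    from gepqsar.karva import ExpressionTree, Node

    def build(j):
        node = Node(toks[j], fset.lookup(toks[j]))
        base = starts[j]
        for k in range(arities[j]):
            node.children.append(build(base + k))
        return node

    return ExpressionTree(build(0))
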