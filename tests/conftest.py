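import numpy as np
import pytest

from forneygraph.graph import build_graph
from forneygraph.models import DTAIPolicySpec, LayerSpec


def seven_factor_spec(rng: np.random.Generator) -> dict:
    """The seven-factor chain over x1..x7 with a single half-edge (x6)."""

    def t(*shape):
        return rng.uniform(0.1, 1.0, shape).tolist()

    return {
        "variables": [
            {"name": f"x{i}", "domain": {"type": "finite", "size": 2}}
            for i in range(1, 8)
        ],
        "factors": [
            {"name": "fa", "kind": "categorical_table", "params": {"table": t(2)}, "variables": ["x1"]},
            {"name": "fb", "kind": "categorical_table", "params": {"table": t(2)}, "variables": ["x2"]},
            {"name": "fc", "kind": "categorical_table", "params": {"table": t(2, 2, 2)}, "variables": ["x1", "x2", "x3"]},
            {"name": "fd", "kind": "categorical_table", "params": {"table": t(2)}, "variables": ["x4"]},
            {"name": "fe", "kind": "categorical_table", "params": {"table": t(2, 2, 2)}, "variables": ["x3", "x4", "x5"]},
            {"name": "ff", "kind": "categorical_table", "params": {"table": t(2, 2, 2)}, "variables": ["x5", "x6", "x7"]},
            {"name": "fg", "kind": "categorical_table", "params": {"table": t(2)}, "variables": ["x7"]},
        ],
    }


def branching_spec(rng: np.random.Generator, size: int = 3) -> dict:
    """Four factors sharing x2 three ways (the equality-normalization case)."""

    def t(*shape):
        return rng.uniform(0.1, 1.0, shape).tolist()

    return {
        "variables": [
            {"name": f"x{i}", "domain": {"type": "finite", "size": size}}
            for i in range(1, 5)
        ],
        "factors": [
            {"name": "fa", "kind": "categorical_table", "params": {"table": t(size, size)}, "variables": ["x1", "x2"]},
            {"name": "fb", "kind": "categorical_table", "params": {"table": t(size, size)}, "variables": ["x2", "x3"]},
            {"name": "fc", "kind": "categorical_table", "params": {"table": t(size, size)}, "variables": ["x2", "x4"]},
        ],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def seven_factor_graph(rng):
    return build_graph(seven_factor_spec(rng))


# ----------------------------------------------------------------------------
# shared hierarchy / DTAI study instances


def copy_hierarchy_specs():
    """A hierarchy in which every layer tends to copy its parent's bit:
    sharp top-down conditioning, weak in-layer likelihoods.  Used for
    information-ordering checks on synthetic data."""

    def copy_cond(n, p):
        t = np.full((n, n), (1 - p) / (n - 1))
        np.fill_diagonal(t, p)
        return t

    A = np.array([[0.6, 0.42], [0.4, 0.58]])
    B = np.zeros((2, 2, 2))
    B[:, :, 0] = copy_cond(2, 0.92)
    B[:, :, 1] = 1 - copy_cond(2, 0.92)
    B[:, :, 1] /= B[:, :, 1].sum(0)
    G = copy_cond(2, 0.9)
    D = copy_cond(2, 0.93)
    top = LayerSpec(2, 2, 2, A=A, B=B, D=np.array([0.5, 0.5]),
                    G=np.array([0.9, 0.1]), steps_per_parent=1)
    mid = LayerSpec(2, 2, 2, A=A, B=B, D=D, G=G, steps_per_parent=2)
    bot = LayerSpec(2, 2, 2, A=A, B=B, D=D, G=G, steps_per_parent=2)
    return [top, mid, bot]


def tree_hierarchy_specs(rng: np.random.Generator):
    """A hierarchy with state-independent control priors: the normalized
    factor graph is a tree, so sum-product marginals are exact."""

    def cond(n, m):
        t = rng.uniform(0.2, 1.0, (n, m))
        return t / t.sum(0)

    def trans(n, u):
        t = rng.uniform(0.2, 1.0, (n, n, u))
        return t / t.sum(0)

    def vec(n):
        t = rng.uniform(0.2, 1.0, n)
        return t / t.sum()

    top = LayerSpec(2, 2, 2, A=cond(2, 2), B=trans(2, 2), D=vec(2),
                    G=vec(2), steps_per_parent=1)
    mid = LayerSpec(2, 2, 2, A=cond(2, 2), B=trans(2, 2), D=cond(2, 2),
                    G=None, steps_per_parent=2)
    bot = LayerSpec(2, 2, 2, A=cond(2, 2), B=trans(2, 2), D=cond(2, 2),
                    G=None, steps_per_parent=2)
    return [top, mid, bot]


def loopy_hierarchy_specs(rng: np.random.Generator):
    """Parent-conditioned control priors make the layers loopy; mild random
    tables keep loopy belief propagation well behaved."""

    def cond(n, m):
        t = rng.uniform(0.2, 1.0, (n, m))
        return t / t.sum(0)

    def trans(n, u):
        t = rng.uniform(0.2, 1.0, (n, n, u))
        return t / t.sum(0)

    def vec(n):
        t = rng.uniform(0.2, 1.0, n)
        return t / t.sum()

    top = LayerSpec(2, 2, 2, A=cond(2, 2), B=trans(2, 2), D=vec(2),
                    G=vec(2), steps_per_parent=1)
    mid = LayerSpec(2, 2, 2, A=cond(2, 2), B=trans(2, 2), D=cond(2, 2),
                    G=cond(2, 2), steps_per_parent=2)
    bot = LayerSpec(2, 2, 2, A=cond(2, 2), B=trans(2, 2), D=cond(2, 2),
                    G=cond(2, 2), steps_per_parent=2)
    return [top, mid, bot]


def goal_seeking_layer(steps_per_parent: int = 1, eps: float = 0.05):
    """A toy control problem: control u deterministically (up to eps)
    steers the state to u's landing state, whose observation the preference
    prior C favors for parent context 0."""
    A = np.array([[1 - eps, eps], [eps, 1 - eps]])
    B = np.zeros((2, 2, 2))
    B[:, :, 0] = np.array([[1 - eps, 1 - eps], [eps, eps]])  # u=0 -> state 0
    B[:, :, 1] = np.array([[eps, eps], [1 - eps, 1 - eps]])  # u=1 -> state 1
    D = np.array([[0.9, 0.1], [0.1, 0.9]])
    layer = LayerSpec(2, 2, 2, A=A, B=B, D=D, G=None,
                      steps_per_parent=steps_per_parent)
    C = [np.array([[0.1, 0.9], [0.9, 0.1]])] * steps_per_parent
    policy = DTAIPolicySpec(C=C, D_bar=[D.copy()] * steps_per_parent)
    return layer, policy
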