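"""Random discrete model generators for oracle cross-checks.

Tree-shaped factorizations over small finite alphabets: every generated
model is acyclic after equality normalization, so sum-product marginals are
exact and can be compared against exhaustive enumeration.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .graph import Graph, build_graph, normalize_shared_variables

__all__ = ["random_tree_spec", "random_tree_graph"]


def random_tree_spec(
    rng: np.random.Generator,
    max_vars: int = 6,
    max_states: int = 4,
    observe_prob: float = 0.3,
) -> dict:
    """A random tree-shaped model specification.

    Each variable beyond the first attaches to one earlier variable through
    a pairwise factor, so the factor graph is a tree (after equality
    expansion of variables shared by several factors).  Some variables are
    observed at random.
    """
    n = int(rng.integers(2, max_vars + 1))
    sizes = [int(rng.integers(2, max_states + 1)) for _ in range(n)]
    variables = []
    factors = []
    for i in range(n):
        v = {"name": f"x{i}", "domain": {"type": "finite", "size": sizes[i]}}
        if i > 0 and rng.random() < observe_prob:
            v["observed"] = int(rng.integers(sizes[i]))
        variables.append(v)
    factors.append(
        {
            "name": "f0",
            "kind": "categorical_table",
            "params": {"table": rng.uniform(0.1, 1.0, sizes[0]).tolist()},
            "variables": ["x0"],
        }
    )
    for i in range(1, n):
        j = int(rng.integers(0, i))
        factors.append(
            {
                "name": f"f{i}",
                "kind": "categorical_table",
                "params": {"table": rng.uniform(0.1, 1.0, (sizes[j], sizes[i])).tolist()},
                "variables": [f"x{j}", f"x{i}"],
            }
        )
    return {"variables": variables, "factors": factors}


def random_tree_graph(
    rng: np.random.Generator,
    max_vars: int = 6,
    max_states: int = 4,
    observe_prob: float = 0.3,
) -> Graph:
    """Build and normalize a random tree model."""
    return normalize_shared_variables(
        build_graph(random_tree_spec(rng, max_vars, max_states, observe_prob))
    )
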