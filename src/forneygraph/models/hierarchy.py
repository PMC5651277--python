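"""Multi-scale hierarchical dynamical systems over finite alphabets.

One top-layer time step owns ``steps_per_parent`` child steps per layer
below it: the parent state conditions the child's initial-state prior D and
(optionally) its control priors G, the child runs a short controlled chain
with likelihood A and transition B, and every child state both emits an
in-layer observation and seeds the next layer down.

Layers are labeled with the authorial acyclic sublayers ('a' = priors,
'b' = chain) so the scheduler can partition them; inference is iterated
top-down prediction followed by bottom-up correction.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ..graph import (
    FactorNode,
    FiniteDomain,
    Graph,
    GraphSpecError,
    VariableEdge,
    normalize_shared_variables,
)
from ..scheduling import (
    Schedule,
    ScheduleStep,
    partition_acyclic,
    run,
    tree_schedule,
)
from .lgds import SyntheticTrajectory

__all__ = [
    "LayerSpec",
    "build_mshd",
    "mshd_infer",
    "simulate_hierarchy",
    "phased_schedule",
    "inherit_sublayer_labels",
]


def _norm_cols(t: np.ndarray) -> bool:
    return bool(np.allclose(t.sum(axis=0), 1.0, atol=1e-8))


@dataclasses.dataclass
class LayerSpec:
    """One layer of the hierarchy (categorical family).

    ``A[o, s]`` likelihood, ``B[s', s, u]`` controlled transition,
    ``D[s0]`` or ``D[s0, parent]`` initial-state prior, ``G`` control prior
    (None for uniform, ``(n_controls,)`` fixed, or ``(n_controls, parent)``
    parent-conditioned), and the temporal nesting ratio ``steps_per_parent``.
    """

    n_states: int
    n_obs: int
    n_controls: int
    A: np.ndarray
    B: np.ndarray
    D: np.ndarray
    G: Optional[np.ndarray] = None
    steps_per_parent: int = 2
    family: str = "categorical"

    def __post_init__(self) -> None:
        if self.family != "categorical":
            raise GraphSpecError(
                "hierarchical builders ship with the categorical family; "
                "use build_lgds_chain for a single Gaussian layer"
            )
        self.A = np.asarray(self.A, float)
        self.B = np.asarray(self.B, float)
        self.D = np.asarray(self.D, float)
        if self.G is not None:
            self.G = np.asarray(self.G, float)
        if self.steps_per_parent < 1:
            raise GraphSpecError("steps_per_parent must be >= 1")
        if self.A.shape != (self.n_obs, self.n_states) or not _norm_cols(self.A):
            raise GraphSpecError("A must be (n_obs, n_states), columns normalized")
        if self.B.shape != (self.n_states, self.n_states, self.n_controls):
            raise GraphSpecError("B must be (n_states, n_states, n_controls)")
        if not np.allclose(self.B.sum(axis=0), 1.0, atol=1e-8):
            raise GraphSpecError("B columns must normalize over the next state")
        if self.D.ndim not in (1, 2) or self.D.shape[0] != self.n_states:
            raise GraphSpecError("D must be (n_states,) or (n_states, n_parent)")
        if not _norm_cols(np.atleast_2d(self.D.T).T):
            raise GraphSpecError("D columns must normalize")
        if self.G is not None and self.G.shape[0] != self.n_controls:
            raise GraphSpecError("G must lead with the control axis")


# ----------------------------------------------------------------------------
# construction


def _add_layer(
    g: Graph,
    specs: Sequence[LayerSpec],
    level: int,
    prefix: str,
    parent_edge: Optional[str],
) -> None:
    """Recursively add one instance of layer ``level`` conditioned on
    ``parent_edge`` (None for the top layer's own prior)."""
    spec = specs[level]
    K = spec.steps_per_parent if level > 0 else 1
    dom_s = FiniteDomain(spec.n_states)
    dom_o = FiniteDomain(spec.n_obs)
    dom_u = FiniteDomain(spec.n_controls)
    lab_a = f"{level}:{prefix}:a"
    lab_b = f"{level}:{prefix}:b"

    def edge(name: str, dom) -> str:
        g.add_edge(VariableEdge(name, name, dom))
        return name

    s = [edge(f"{prefix}_s{k}", dom_s) for k in range(K + 1)]
    u = [edge(f"{prefix}_u{k}", dom_u) for k in range(K)]
    o = [edge(f"{prefix}_o{k}", dom_o) for k in range(1, K + 1)]

    # priors sublayer: initial state and controls, conditioned on the parent
    if parent_edge is None:
        if spec.D.ndim != 1:
            raise GraphSpecError("top layer D must be unconditional")
        g.add_node(FactorNode(f"{prefix}_D", "categorical_table",
                              {"table": spec.D}, [s[0]],
                              metadata={"sublayer": lab_a}))
    else:
        if spec.D.ndim != 2:
            raise GraphSpecError("child layer D must be parent-conditioned")
        g.add_node(FactorNode(f"{prefix}_D", "categorical_table",
                              {"table": spec.D}, [s[0], parent_edge],
                              metadata={"sublayer": lab_a}))
    for k in range(K):
        if spec.G is None:
            table = np.full(spec.n_controls, 1.0 / spec.n_controls)
            iface = [u[k]]
        elif spec.G.ndim == 1:
            table, iface = spec.G, [u[k]]
        else:
            if parent_edge is None:
                raise GraphSpecError("top layer G cannot be parent-conditioned")
            table, iface = spec.G, [u[k], parent_edge]
        g.add_node(FactorNode(f"{prefix}_G{k}", "categorical_table",
                              {"table": table}, iface,
                              metadata={"sublayer": lab_a}))

    # state-space sublayer: controlled transitions and in-layer likelihoods
    for k in range(1, K + 1):
        g.add_node(FactorNode(f"{prefix}_B{k}", "categorical_table",
                              {"table": spec.B}, [s[k], s[k - 1], u[k - 1]],
                              metadata={"sublayer": lab_b}))
        g.add_node(FactorNode(f"{prefix}_A{k}", "categorical_table",
                              {"table": spec.A}, [o[k - 1], s[k]],
                              metadata={"sublayer": lab_b}))

    # children hang off states s_0 ... s_{K-1}
    if level + 1 < len(specs):
        for k in range(K):
            _add_layer(g, specs, level + 1, f"{prefix}k{k}", s[k])


def attach_observations(g: Graph, observations: Dict[str, int]) -> None:
    for name, val in sorted(observations.items()):
        e = g.edges[name]
        e.observed_value = int(val)
        g.add_node(FactorNode(f"obs_{name}", "observation_terminal", {}, [name]))


def inherit_sublayer_labels(g: Graph) -> None:
    """Give equality/terminal nodes the sublayer of their first labeled
    neighbor (breadth-first until stable)."""
    changed = True
    while changed:
        changed = False
        for n in sorted(g.nodes.values(), key=lambda n: n.id):
            if n.metadata.get("sublayer") is not None:
                continue
            for eid in n.interface:
                for nb in g.edges[eid].endpoints:
                    lab = g.nodes[nb].metadata.get("sublayer")
                    if nb != n.id and lab is not None:
                        n.metadata["sublayer"] = lab
                        changed = True
                        break
                if n.metadata.get("sublayer") is not None:
                    break


def build_mshd(
    specs: Sequence[LayerSpec],
    observations: Optional[Dict[str, int]] = None,
) -> Graph:
    """Build the hierarchy: layer 0 is the (single-step) top layer; each
    deeper layer runs ``steps_per_parent`` steps per parent state.  Edge
    names carry the context: ``L_s0`` (top state), ``Lk0_s1`` (child of the
    top state at step 0), ``Lk0k1_o2`` etc.  Observations are given by edge
    name; state edges may be clamped the same way."""
    if not specs:
        raise GraphSpecError("need at least one layer")
    g = Graph()
    _add_layer(g, list(specs), 0, "L", None)
    if observations:
        attach_observations(g, observations)
    g = normalize_shared_variables(g)
    inherit_sublayer_labels(g)
    return g


# ----------------------------------------------------------------------------
# inference


def phased_schedule(g: Graph) -> Schedule:
    """Top-down prediction then bottom-up correction over the labeled
    acyclic sublayers (one sweep; iterate via ``run``)."""
    subs = partition_acyclic(g)  # label-sorted: depth, then a before b
    half_in_g = set(g.half_edges())

    def sub_steps(sub: Graph) -> List[ScheduleStep]:
        sched = tree_schedule(sub)
        return [
            st for st in sched.steps
            if not (st.node_id is None and st.edge_id not in half_in_g)
        ]

    steps: List[ScheduleStep] = []
    for sub in subs:
        steps.extend(sub_steps(sub))
    for sub in reversed(subs):
        steps.extend(sub_steps(sub))
    return Schedule(steps, metadata="phased top-down / bottom-up sweep")


def mshd_infer(
    g: Graph,
    max_sweeps: int = 50,
    tol: float = 1e-8,
):
    """Iterate phased sweeps to convergence; returns (marginals, trace,
    converged)."""
    sched = phased_schedule(g)
    return run(g, sched, max_sweeps=max_sweeps, tol=tol)


# ----------------------------------------------------------------------------
# synthetic data


def simulate_hierarchy(specs: Sequence[LayerSpec], seed: int) -> SyntheticTrajectory:
    """Ancestral sampling through the hierarchy; values keyed by edge name."""
    rng = np.random.default_rng(seed)
    states: Dict[str, int] = {}
    controls: Dict[str, int] = {}
    observations: Dict[str, int] = {}

    def draw(p: np.ndarray) -> int:
        return int(rng.choice(p.shape[0], p=p / p.sum()))

    def sample_layer(level: int, prefix: str, parent_val: Optional[int]) -> None:
        spec = specs[level]
        K = spec.steps_per_parent if level > 0 else 1
        if parent_val is None:
            s_val = draw(spec.D)
        else:
            s_val = draw(spec.D[:, parent_val])
        states[f"{prefix}_s0"] = s_val
        s_seq = [s_val]
        for k in range(K):
            if spec.G is None:
                u_val = int(rng.integers(spec.n_controls))
            elif spec.G.ndim == 1:
                u_val = draw(spec.G)
            else:
                u_val = draw(spec.G[:, parent_val])
            controls[f"{prefix}_u{k}"] = u_val
            nxt = draw(spec.B[:, s_seq[-1], u_val])
            states[f"{prefix}_s{k + 1}"] = nxt
            s_seq.append(nxt)
            observations[f"{prefix}_o{k + 1}"] = draw(spec.A[:, nxt])
        if level + 1 < len(specs):
            for k in range(K):
                sample_layer(level + 1, f"{prefix}k{k}", s_seq[k])

    sample_layer(0, "L", None)
    return SyntheticTrajectory(
        states=states, observations=observations, seed=seed, controls=controls
    )
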