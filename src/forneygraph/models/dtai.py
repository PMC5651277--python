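"""Deep temporal active inference: a hierarchical layer whose control prior
emerges from inference in a generative policy model.

Each policy layer holds three sublayers: (a) preference priors C (desired
observations) and D-bar (desired states) conditioned on the parent state,
together with the executed chain's initial-state prior; (b) a mirror copy
of the state-space model over bar variables, used to simulate the future;
(c) the executed chain terminated by actual observations.  Control edges
are shared between the mirror and executed transition factors, so the
posterior over a control combines the policy-derived forward message with
the evidence-derived backward message.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..beliefs import CategoricalBelief, Marginal, PointMass
from ..free_energy import FreeEnergyReport, free_energy, proposal_from_marginals
from ..graph import (
    FactorNode,
    FiniteDomain,
    Graph,
    GraphSpecError,
    VariableEdge,
    normalize_shared_variables,
)
from ..scheduling import (
    MessageState,
    Schedule,
    ScheduleStep,
    execute_step,
    marginal_of,
    partition_acyclic,
    tree_schedule,
)
from .hierarchy import LayerSpec, attach_observations, inherit_sublayer_labels

__all__ = [
    "DTAIPolicySpec",
    "build_dtai",
    "dtai_step",
    "DTAIStepResult",
    "update_priors",
]


@dataclasses.dataclass
class DTAIPolicySpec:
    """Preference priors of the generative policy model.

    ``C[k]`` with shape (n_obs, n_parent): preferred observations at mirror
    step k+1; ``D_bar[k]`` with shape (n_states, n_parent): preferred states
    at mirror step k.  The mirror chain's A/B are read-only views of the
    executed chain's parameters (tied by construction).
    """

    C: List[np.ndarray]
    D_bar: List[np.ndarray]

    def validate(self, spec: LayerSpec, n_parent: int) -> None:
        K = spec.steps_per_parent
        if len(self.C) != K or len(self.D_bar) != K:
            raise GraphSpecError("need one C per step and one D_bar per step")
        for Ck in self.C:
            if np.asarray(Ck).shape != (spec.n_obs, n_parent):
                raise GraphSpecError("C must be (n_obs, n_parent)")
        for Dk in self.D_bar:
            if np.asarray(Dk).shape != (spec.n_states, n_parent):
                raise GraphSpecError("D_bar must be (n_states, n_parent)")


def build_dtai(
    layer: LayerSpec,
    policy: DTAIPolicySpec,
    n_parent: int,
    parent_value: Optional[int] = None,
    observations: Optional[Dict[str, int]] = None,
    prefix: str = "P",
) -> Graph:
    """One active-inference layer below a parent state edge ``{prefix}_ctx``.

    The parent state may be clamped to ``parent_value`` (known context) or
    left as an open half-edge toward the superior layer.  The mirror B/A
    tables are the same arrays as the executed ones (tied parameters).
    """
    policy.validate(layer, n_parent)
    if layer.G is not None:
        raise GraphSpecError(
            "a DTAI layer has no stored control prior; the policy model is it"
        )
    g = Graph()
    K = layer.steps_per_parent
    dom_s = FiniteDomain(layer.n_states)
    dom_o = FiniteDomain(layer.n_obs)
    dom_u = FiniteDomain(layer.n_controls)
    dom_p = FiniteDomain(n_parent)
    lab = lambda s: f"0:{prefix}:{s}"

    def edge(name: str, dom) -> str:
        g.add_edge(VariableEdge(name, name, dom))
        return name

    ctx = edge(f"{prefix}_ctx", dom_p)
    s = [edge(f"{prefix}_s{k}", dom_s) for k in range(K + 1)]
    sb = [edge(f"{prefix}_sb{k}", dom_s) for k in range(K + 1)]
    u = [edge(f"{prefix}_u{k}", dom_u) for k in range(K)]
    o = [edge(f"{prefix}_o{k}", dom_o) for k in range(1, K + 1)]
    ob = [edge(f"{prefix}_ob{k}", dom_o) for k in range(1, K + 1)]

    # (a) priors: executed initial state, preferred states, preferred obs
    g.add_node(FactorNode(f"{prefix}_D", "categorical_table",
                          {"table": layer.D}, [s[0], ctx],
                          metadata={"sublayer": lab("a")}))
    for k in range(K):
        g.add_node(FactorNode(f"{prefix}_Dbar{k}", "categorical_table",
                              {"table": np.asarray(policy.D_bar[k], float)},
                              [sb[k], ctx], metadata={"sublayer": lab("a")}))
    for k in range(1, K + 1):
        g.add_node(FactorNode(f"{prefix}_C{k}", "categorical_table",
                              {"table": np.asarray(policy.C[k - 1], float)},
                              [ob[k - 1], ctx], metadata={"sublayer": lab("a")}))
    # (b) mirror chain (tied tables simulate the future)
    for k in range(1, K + 1):
        g.add_node(FactorNode(f"{prefix}_Bbar{k}", "categorical_table",
                              {"table": layer.B}, [sb[k], sb[k - 1], u[k - 1]],
                              metadata={"sublayer": lab("b")}))
        g.add_node(FactorNode(f"{prefix}_Abar{k}", "categorical_table",
                              {"table": layer.A}, [ob[k - 1], sb[k]],
                              metadata={"sublayer": lab("b")}))
    # (c) executed chain
    for k in range(1, K + 1):
        g.add_node(FactorNode(f"{prefix}_B{k}", "categorical_table",
                              {"table": layer.B}, [s[k], s[k - 1], u[k - 1]],
                              metadata={"sublayer": lab("c")}))
        g.add_node(FactorNode(f"{prefix}_A{k}", "categorical_table",
                              {"table": layer.A}, [o[k - 1], s[k]],
                              metadata={"sublayer": lab("c")}))

    obs = dict(observations or {})
    if parent_value is not None:
        obs[ctx] = int(parent_value)
    if obs:
        attach_observations(g, obs)
    g = normalize_shared_variables(g)
    inherit_sublayer_labels(g)
    return g


@dataclasses.dataclass
class DTAIStepResult:
    control_marginals: Dict[str, np.ndarray]
    policy_control_marginals: Dict[str, np.ndarray]
    state_marginals: Dict[str, Marginal]
    report: FreeEnergyReport
    marginals: Dict[str, Marginal]


def _sub_steps(g: Graph, sub: Graph, drop_observation_steps: bool = False
               ) -> List[ScheduleStep]:
    half_in_g = set(g.half_edges())
    steps = []
    for st in tree_schedule(sub).steps:
        if st.node_id is None and st.edge_id not in half_in_g:
            continue
        if drop_observation_steps and st.node_id is not None and \
                g.nodes[st.node_id].kind == "observation_terminal" and \
                not st.edge_id.endswith("ctx") and "ctx" not in st.edge_id:
            continue
        steps.append(st)
    return steps


def _control_probs(g: Graph, state: MessageState, prefix: str) -> Dict[str, np.ndarray]:
    out = {}
    for eid in sorted(g.edges):
        e = g.edges[eid]
        if e.origin.startswith(f"{prefix}_u") and e.origin == e.name:
            m = marginal_of(g, state, eid)
            b = m.belief
            if isinstance(b, CategoricalBelief):
                out[e.origin] = b.probs
            elif isinstance(b, PointMass):
                p = np.zeros(e.domain.size)
                p[int(b.value)] = 1.0
                out[e.origin] = p
    return out


def dtai_step(
    g: Graph,
    prefix: str = "P",
    extra_passes: int = 1,
    sweeps: int = 1,
) -> DTAIStepResult:
    """Run the phased schedule of one active-inference layer.

    Phases: (i) priors from the parent state [sublayer a]; (ii)-(iii)
    forward simulation of the mirror chain and the backward pass that treats
    the C/D-bar priors as observations [sublayer b]; (iv) control inference
    -- the policy-derived control marginals are recorded here, before any
    evidence; (v) executed-chain forward prediction [sublayer c without
    observation terminals]; (vi) evidence absorption and backward
    correction [sublayer c in full]; (vii) upward corrections re-entering
    the mirror/priors sublayers (``extra_passes`` times).  The free energy
    is evaluated after the prediction and after the correction phases.
    """
    subs = partition_acyclic(g)
    by_label: Dict[str, Graph] = {}
    for sub in subs:
        labels = {n.metadata.get("sublayer") for n in sub.nodes.values()}
        (label,) = labels
        by_label[label.rsplit(":", 1)[-1]] = sub
    for need in ("a", "b", "c"):
        if need not in by_label:
            raise GraphSpecError(f"missing sublayer {need!r}; build with build_dtai")

    state = MessageState()
    # phases (i)-(iv): priors, mirror simulation, policy-derived controls
    for st in _sub_steps(g, by_label["a"]):
        execute_step(g, state, st, rescale=True)
    for st in _sub_steps(g, by_label["b"]):
        execute_step(g, state, st, rescale=True)
    policy_controls = _control_probs(g, state, prefix)

    # phase (v): executed-chain prediction (observation terminals withheld)
    for st in _sub_steps(g, by_label["c"], drop_observation_steps=True):
        execute_step(g, state, st, rescale=True)
    marg_pred = {eid: marginal_of(g, state, eid) for eid in sorted(g.edges)}
    f_pred = free_energy(g, proposal_from_marginals(g, marg_pred)).F

    # phase (vi): evidence absorption and backward correction
    for st in _sub_steps(g, by_label["c"]):
        execute_step(g, state, st, rescale=True)
    marg_corr = {eid: marginal_of(g, state, eid) for eid in sorted(g.edges)}
    f_corr = free_energy(g, proposal_from_marginals(g, marg_corr)).F

    # phase (vii): push corrections up through the mirror and priors
    for _ in range(max(extra_passes, 0)):
        for st in _sub_steps(g, by_label["b"]):
            execute_step(g, state, st, rescale=True)
        for st in _sub_steps(g, by_label["a"]):
            execute_step(g, state, st, rescale=True)
    # optional additional whole-cycle sweeps toward the loopy fixed point
    for _ in range(max(sweeps - 1, 0)):
        for lab in ("a", "b", "c", "b", "a"):
            for st in _sub_steps(g, by_label[lab]):
                execute_step(g, state, st, rescale=True)

    marginals = {eid: marginal_of(g, state, eid) for eid in sorted(g.edges)}
    controls = _control_probs(g, state, prefix)
    states = {
        eid: m for eid, m in marginals.items()
        if g.edges[eid].origin.startswith(f"{prefix}_s")
        and g.edges[eid].origin == g.edges[eid].name
    }
    report = FreeEnergyReport(F=f_corr, trace=[f_pred, f_corr])
    return DTAIStepResult(
        control_marginals=controls,
        policy_control_marginals=policy_controls,
        state_marginals=states,
        report=report,
        marginals=marginals,
    )


# ----------------------------------------------------------------------------
# prior learning


def update_priors(
    g: Graph,
    node_id: str,
    child_probs: np.ndarray,
    parent_probs: Optional[np.ndarray],
    learning_rate: float,
) -> None:
    """Conjugate (pseudo-count) update of a C or D prior factor.

    Counts are incremented by ``learning_rate`` times the corrected marginal
    mass and the table renormalized per parent column; the total pseudo-count
    grows by exactly ``learning_rate`` per update.
    """
    if learning_rate < 0:
        raise GraphSpecError("learning_rate must be nonnegative")
    node = g.nodes[node_id]
    table = np.asarray(node.parameters["table"], float)
    counts = node.parameters.get("counts")
    if counts is None:
        counts = table.copy()
    child_probs = np.asarray(child_probs, float)
    if table.ndim == 2:
        if parent_probs is None:
            raise GraphSpecError("parent marginal required for a conditioned prior")
        increment = np.outer(child_probs, np.asarray(parent_probs, float))
    else:
        increment = child_probs
    counts = counts + learning_rate * increment
    node.parameters["counts"] = counts
    if table.ndim == 2:
        node.parameters["table"] = counts / counts.sum(axis=0, keepdims=True)
    else:
        node.parameters["table"] = counts / counts.sum()
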