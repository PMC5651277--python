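"""Message schedules: generation, execution, convergence monitoring.

A schedule is an ordered list of (node, target-edge, rule) steps.  Tree
schedules run terminals-to-target in dependency order and are exact on
acyclic graphs (sum-product theorem); full sweeps cover both directions of
every edge and are iterated to a fixed point on loopy graphs, starting from
vacuous messages.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .beliefs import (
    VACUOUS,
    Belief,
    CategoricalBelief,
    GaussianBelief,
    Marginal,
    Message,
    NotNormalizableError,
    PointMass,
    Vacuous,
    combine,
)
from .graph import CompositeNode, Graph, GraphSpecError
from . import rules as _rules

__all__ = [
    "ScheduleStep",
    "Schedule",
    "ScheduleTrace",
    "MessageState",
    "ScheduleError",
    "tree_schedule",
    "full_sweep_schedule",
    "partition_acyclic",
    "run",
    "composite_message",
    "subgraph_of",
]


class ScheduleError(GraphSpecError):
    pass


@dataclasses.dataclass(frozen=True)
class ScheduleStep:
    #: producing node id; None injects the vacuous half-edge message
    node_id: Optional[str]
    edge_id: str
    rule_tag: str = "sum_product"


@dataclasses.dataclass
class Schedule:
    steps: List[ScheduleStep]
    metadata: str = ""

    def __len__(self) -> int:
        return len(self.steps)


@dataclasses.dataclass
class ScheduleTrace:
    """Per-step message snapshots and per-sweep convergence diagnostics."""

    rows: List[dict] = dataclasses.field(default_factory=list)
    sweep_deltas: List[float] = dataclasses.field(default_factory=list)
    free_energy: List[float] = dataclasses.field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _tag_for(g: Graph, node_id: str) -> str:
    kind = g.nodes[node_id].kind
    if kind == "observation_terminal":
        return "observation"
    if len(g.nodes[node_id].interface) == 1:
        return "terminal"
    return "sum_product"


# ----------------------------------------------------------------------------
# schedule generation


def tree_schedule(g: Graph, targets: Optional[Sequence[str]] = None) -> Schedule:
    """Post-order schedule from terminals/half-edges toward the targets.

    Every target edge receives both directions.  Raises on cyclic graphs.
    """
    if targets is None:
        targets = sorted(g.edges)
    steps: List[ScheduleStep] = []
    have: set = set()
    in_progress: set = set()

    def need(edge_id: str, toward: Optional[str]) -> None:
        key = (edge_id, toward)
        if key in have:
            return
        eps = g.edges[edge_id].endpoints
        if len(eps) > 2:
            raise ScheduleError(f"edge {edge_id!r} not normalized (>2 endpoints)")
        producers = [n for n in eps if n != toward]
        if not producers:
            # inbound from outside a half-edge: vacuous injection
            steps.append(ScheduleStep(None, edge_id, "half_edge"))
            have.add(key)
            return
        producer = producers[0]
        if key in in_progress:
            raise ScheduleError("graph is cyclic; partition it first")
        in_progress.add(key)
        for other in g.nodes[producer].interface:
            if other != edge_id:
                need(other, producer)
        in_progress.discard(key)
        steps.append(ScheduleStep(producer, edge_id, _tag_for(g, producer)))
        have.add(key)

    for t in sorted(targets):
        eps = g.edges[t].endpoints
        if len(eps) == 2:
            need(t, eps[0])
            need(t, eps[1])
        elif len(eps) == 1:
            need(t, eps[0])  # vacuous from outside
            need(t, None)  # outgoing through the factor
        else:
            raise ScheduleError(f"edge {t!r} has no endpoints")
    return Schedule(steps, metadata=f"tree schedule for {len(list(targets))} targets")


def full_sweep_schedule(g: Graph, rule_tag: str = "sum_product") -> Schedule:
    """One sweep covering both directions of every edge (2 x |edges| steps).

    On acyclic graphs the steps come out in dependency order (it reduces to a
    tree schedule over all edges); on loopy graphs steps are ordered
    lexicographically by (node, edge) and consume the current message state.
    """
    try:
        sched = tree_schedule(g, sorted(g.edges))
        sched.metadata = "full sweep (tree order)"
        return sched
    except ScheduleError:
        pass
    steps: List[ScheduleStep] = []
    for e in sorted(g.edges):
        if len(g.edges[e].endpoints) == 1:
            steps.append(ScheduleStep(None, e, "half_edge"))
    for nid in sorted(g.nodes):
        node = g.nodes[nid]
        tag = _tag_for(g, nid)
        if tag == "sum_product":
            tag = rule_tag
        for e in node.interface:
            steps.append(ScheduleStep(nid, e, tag))
    return Schedule(steps, metadata="full sweep (loopy, lexicographic)")


def subgraph_of(g: Graph, node_ids: Sequence[str]) -> Graph:
    """Node-induced subgraph; cross-boundary edges become half-edges."""
    node_ids = set(node_ids)
    sub = Graph()
    for e in sorted(g.edges.values(), key=lambda e: e.id):
        inside = [n for n in e.endpoints if n in node_ids]
        if inside:
            sub.edges[e.id] = dataclasses.replace(e, endpoints=inside)
    for nid in sorted(node_ids):
        n = g.nodes[nid]
        sub.nodes[nid] = dataclasses.replace(
            n, interface=list(n.interface), parameters=dict(n.parameters),
            metadata=dict(n.metadata),
        )
    return sub


def partition_acyclic(g: Graph) -> List[Graph]:
    """Edge-disjoint cover of the graph by acyclic (tree-schedulable) subgraphs.

    Builders may label nodes with ``metadata['sublayer']`` (the authorial
    partition, e.g. the 2a/2b split of a hierarchical layer); labels are
    honored when present.  Otherwise nodes are assigned greedily, keeping
    each subgraph a forest via union-find.
    """
    labels = {n.id: n.metadata.get("sublayer") for n in g.nodes.values()}
    if all(v is not None for v in labels.values()) and g.nodes:
        groups: Dict[str, List[str]] = {}
        for nid, lab in sorted(labels.items()):
            groups.setdefault(lab, []).append(nid)
        subs = [subgraph_of(g, nids) for _, nids in sorted(groups.items())]
        for s in subs:
            if not s.is_acyclic():
                raise ScheduleError("labeled sublayer is not acyclic")
        return subs

    # greedy forest cover
    parents: List[Dict[str, str]] = []  # union-find per subgraph over edge ids
    members: List[List[str]] = []

    def find(p: Dict[str, str], x: str) -> str:
        while p.setdefault(x, x) != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    for nid in sorted(g.nodes):
        placed = False
        node = g.nodes[nid]
        for p, m in zip(parents, members):
            roots = [find(p, e) for e in node.interface if e in p]
            if len(roots) == len(set(roots)):
                base = find(p, node.interface[0]) if node.interface else None
                for e in node.interface:
                    p[find(p, e)] = base if base else find(p, e)
                m.append(nid)
                placed = True
                break
        if not placed:
            p: Dict[str, str] = {}
            base = None
            for e in node.interface:
                if base is None:
                    base = find(p, e)
                else:
                    p[find(p, e)] = base
            parents.append(p)
            members.append([nid])
    return [subgraph_of(g, m) for m in members]


# ----------------------------------------------------------------------------
# execution


class MessageState:
    """Directed messages, keyed by (edge id, toward-node id or None)."""

    def __init__(self) -> None:
        self.messages: Dict[Tuple[str, Optional[str]], Belief] = {}

    def get(self, edge_id: str, toward: Optional[str]) -> Belief:
        return self.messages.get((edge_id, toward), VACUOUS)

    def set(self, edge_id: str, toward: Optional[str], belief: Belief) -> None:
        self.messages[(edge_id, toward)] = belief

    def inbound_for(self, g: Graph, node_id: str, target: str) -> Dict[str, Belief]:
        node = g.nodes[node_id]
        return {
            e: self.get(e, node_id) for e in node.interface if e != target
        }


def marginal_of(g: Graph, state: MessageState, edge_id: str) -> Marginal:
    eps = g.edges[edge_id].endpoints
    fwd = Message(edge_id, eps[0], state.get(edge_id, eps[0]))
    bwd_toward = eps[1] if len(eps) == 2 else None
    bwd = Message(edge_id, bwd_toward, state.get(edge_id, bwd_toward))
    return combine(fwd, bwd)


def _params_of(b: Belief) -> np.ndarray:
    if isinstance(b, GaussianBelief):
        return np.concatenate([b.mean.ravel(), b.cov.ravel()])
    if isinstance(b, CategoricalBelief):
        return b.probs
    if isinstance(b, PointMass):
        return np.atleast_1d(np.asarray(b.value, dtype=float))
    return np.array([])


def _damp(old: Belief, new: Belief, damping: float) -> Belief:
    if damping <= 0 or old is None:
        return new
    if isinstance(old, CategoricalBelief) and isinstance(new, CategoricalBelief):
        lw = damping * old.log_weights + (1 - damping) * new.log_weights
        return CategoricalBelief(log_weights=lw)
    if isinstance(old, GaussianBelief) and isinstance(new, GaussianBelief):
        return GaussianBelief(
            damping * old.W + (1 - damping) * new.W,
            damping * old.h + (1 - damping) * new.h,
            damping * old.g + (1 - damping) * new.g,
        )
    return new


def _rescaled(b: Belief) -> Belief:
    """Strip the absolute scale from a belief (used in iterated sweeps,
    where scales otherwise compound around loops and destroy precision)."""
    if isinstance(b, CategoricalBelief):
        return CategoricalBelief(log_weights=b.log_weights - b.log_weights.max())
    if isinstance(b, GaussianBelief):
        try:
            return b.normalized() if b.is_proper else GaussianBelief(b.W, b.h, 0.0)
        except np.linalg.LinAlgError:
            return GaussianBelief(b.W, b.h, 0.0)
    if isinstance(b, PointMass):
        return PointMass(b.value)
    return b


def execute_step(g: Graph, state: MessageState, step: ScheduleStep,
                 damping: float = 0.0, rescale: bool = False) -> Message:
    if step.node_id is None:
        eps = g.edges[step.edge_id].endpoints
        msg = Message(step.edge_id, eps[0], VACUOUS)
        state.set(step.edge_id, eps[0], msg.belief)
        return msg
    node = g.nodes[step.node_id]
    if step.rule_tag == "variational":
        # variational rules consume current marginals on the other edges
        marg: Dict[str, Belief] = {}
        for e in node.interface:
            if e == step.edge_id:
                continue
            try:
                marg[e] = marginal_of(g, state, e).belief
            except NotNormalizableError:
                marg[e] = VACUOUS
        res = _rules.variational(node, marg, step.edge_id, g)
    else:
        inbound = state.inbound_for(g, step.node_id, step.edge_id)
        res = _rules.sum_product(node, inbound, step.edge_id, g)
    old = state.messages.get((res.message.edge_id, res.message.toward))
    belief = res.message.belief
    if rescale:
        belief = _rescaled(belief)
    belief = _damp(old, belief, damping)
    state.set(res.message.edge_id, res.message.toward, belief)
    return Message(res.message.edge_id, res.message.toward, belief)


def run(
    g: Graph,
    schedule: Schedule,
    max_sweeps: int = 50,
    tol: float = 1e-8,
    state: Optional[MessageState] = None,
    damping: float = 0.0,
    free_energy_hook: Optional[Callable[[Dict[str, Marginal]], float]] = None,
    record_trace: bool = False,
) -> Tuple[Dict[str, Marginal], ScheduleTrace, bool]:
    """Execute a schedule repeatedly until the marginals stop changing.

    Returns (marginals for every edge, trace, converged flag).  Uninitialized
    inbound messages default to vacuous.
    """
    if state is None:
        state = MessageState()
    trace = ScheduleTrace()
    prev: Dict[str, np.ndarray] = {}
    converged = False
    for sweep in range(max_sweeps):
        for step in schedule.steps:
            try:
                msg = execute_step(g, state, step, damping, rescale=True)
            except NotNormalizableError as err:
                raise ScheduleError(
                    f"divergence at step ({step.node_id}, {step.edge_id}): {err}"
                ) from err
            if record_trace:
                b = msg.belief
                trace.rows.append(
                    {
                        "sweep": sweep,
                        "node": step.node_id,
                        "edge": msg.edge_id,
                        "rule": step.rule_tag,
                        "family": type(b).__name__,
                        "params": np.array2string(_params_of(b), precision=6),
                    }
                )
        marginals: Dict[str, Marginal] = {}
        delta = 0.0
        for eid in sorted(g.edges):
            try:
                marg = marginal_of(g, state, eid)
            except NotNormalizableError:
                continue  # no information yet on this edge
            marginals[eid] = marg
            p = _params_of(marg.belief)
            if eid in prev and prev[eid].shape == p.shape:
                delta = max(delta, float(np.max(np.abs(p - prev[eid]))) if p.size else 0.0)
            else:
                delta = np.inf
            prev[eid] = p
        trace.sweep_deltas.append(delta)
        if free_energy_hook is not None:
            trace.free_energy.append(free_energy_hook(marginals))
        if delta < tol:
            converged = True
            break
    return marginals, trace, converged


# ----------------------------------------------------------------------------
# composite nodes: messages by internal passing


def composite_message(comp: CompositeNode, inbound: Dict[str, Belief],
                      target: str) -> Belief:
    """Outgoing message of a composite node on a boundary edge.

    Incoming messages are clamped on the other boundary edges and messages
    are passed internally (one tree pass on acyclic interiors, iterated
    sweeps otherwise).
    """
    if target not in comp.boundary:
        raise ScheduleError(f"{target!r} is not a boundary edge of the composite")
    inner = comp.inner
    state = MessageState()
    for b in comp.boundary:
        if b == target:
            continue
        ep = inner.edges[b].endpoints[0]
        state.set(b, ep, inbound.get(b, VACUOUS))
    if inner.is_acyclic():
        sched = tree_schedule(inner, targets=[target])
        # boundary inbound already present; drop steps that would overwrite it
        sched = Schedule(
            [
                s
                for s in sched.steps
                if not (s.node_id is None and s.edge_id in comp.boundary
                        and s.edge_id != target)
            ],
            sched.metadata,
        )
        for step in sched.steps:
            execute_step(inner, state, step)
    else:
        sched = full_sweep_schedule(inner)
        sched = Schedule(
            [s for s in sched.steps
             if not (s.node_id is None and s.edge_id in comp.boundary)],
            sched.metadata,
        )
        run(inner, sched, max_sweeps=50, tol=1e-10, state=state)
    return state.get(target, None)
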