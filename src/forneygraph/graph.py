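"""Forney-style factor graphs: nodes are factors, edges are variables.

A variable edge attaches to at most two factor nodes; variables shared by
more than two factors are rewritten with equality (branching) nodes by
:func:`normalize_shared_variables`.  Subsets of nodes can be closed into
composite nodes (:func:`close_box`) whose outgoing messages marginalize the
boxed product over the interior.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from typing import Dict, Iterable, List, Optional, Sequence, Set, Union

import networkx as nx
import numpy as np

__all__ = [
    "RealDomain",
    "FiniteDomain",
    "VariableEdge",
    "FactorNode",
    "LogicalFactor",
    "Graph",
    "CompositeNode",
    "GraphSpecError",
    "build_graph",
    "normalize_shared_variables",
    "close_box",
    "validate",
    "to_dot",
    "graph_to_dict",
]

# Node kinds and their interface arity (None = variable arity).
NODE_ARITY = {
    "addition": 3,
    "subtraction": 3,
    "gain": 2,
    "equality": 3,
    "gaussian_prior": 1,
    "categorical_table": None,
    "custom_table": None,
    "observation_terminal": 1,
    "composite": None,
}


class GraphSpecError(ValueError):
    """Raised for malformed model specifications or graph surgery errors."""


@dataclasses.dataclass(frozen=True)
class RealDomain:
    """Continuous real vector domain of a given dimension."""

    dim: int = 1


@dataclasses.dataclass(frozen=True)
class FiniteDomain:
    """Finite alphabet {0, ..., size-1}."""

    size: int


Domain = Union[RealDomain, FiniteDomain]


@dataclasses.dataclass
class VariableEdge:
    id: str
    name: str
    domain: Domain
    endpoints: List[str] = dataclasses.field(default_factory=list)
    observed_value: Optional[Union[int, float, np.ndarray]] = None
    #: name of the original variable this edge is a copy of (equality expansion)
    origin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.origin is None:
            self.origin = self.name

    @property
    def is_half_edge(self) -> bool:
        return len(self.endpoints) == 1

    @property
    def is_auxiliary(self) -> bool:
        """True for equality-expansion copies (reported but flagged as such)."""
        return self.origin != self.name


@dataclasses.dataclass
class FactorNode:
    id: str
    kind: str
    parameters: dict = dataclasses.field(default_factory=dict)
    interface: List[str] = dataclasses.field(default_factory=list)
    metadata: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class LogicalFactor:
    """A conditional density of the model the graph represents.

    Free-energy evaluation works on these rather than on the primitive
    (delta-decomposed, equality-expanded) nodes.  ``variables`` are original
    variable names.  Kinds: ``categorical`` (params: table, axes follow
    ``variables``), ``gaussian_prior`` (mean, cov), ``linear_gaussian``
    (child = gain * parent + noise; params: gain or gain_var, noise_cov).
    """

    kind: str
    variables: tuple
    params: dict


class Graph:
    """A Forney-style factor graph."""

    def __init__(self) -> None:
        self.nodes: Dict[str, FactorNode] = {}
        self.edges: Dict[str, VariableEdge] = {}
        #: optional logical factorization for free-energy evaluation
        self.logical_factors: Optional[List[LogicalFactor]] = None

    # -- construction -----------------------------------------------------
    def add_edge(self, edge: VariableEdge) -> VariableEdge:
        if edge.id in self.edges:
            raise GraphSpecError(f"duplicate edge id {edge.id!r}")
        self.edges[edge.id] = edge
        return edge

    def add_node(self, node: FactorNode) -> FactorNode:
        if node.id in self.nodes:
            raise GraphSpecError(f"duplicate node id {node.id!r}")
        arity = NODE_ARITY.get(node.kind, -1)
        if arity == -1:
            raise GraphSpecError(f"unknown node kind {node.kind!r}")
        self.nodes[node.id] = node
        for eid in node.interface:
            self.edges[eid].endpoints.append(node.id)
        return node

    def copy(self) -> "Graph":
        g = Graph()
        for e in self.edges.values():
            g.edges[e.id] = dataclasses.replace(e, endpoints=list(e.endpoints))
        for n in self.nodes.values():
            g.nodes[n.id] = dataclasses.replace(
                n,
                interface=list(n.interface),
                parameters=dict(n.parameters),
                metadata=dict(n.metadata),
            )
        if self.logical_factors is not None:
            g.logical_factors = list(self.logical_factors)
        return g

    # -- queries ----------------------------------------------------------
    def other_endpoint(self, edge_id: str, node_id: str) -> Optional[str]:
        eps = self.edges[edge_id].endpoints
        others = [n for n in eps if n != node_id]
        if len(others) > 1:  # shared variable before normalization
            raise GraphSpecError(f"edge {edge_id!r} has >2 endpoints; normalize first")
        return others[0] if others else None

    def half_edges(self) -> List[str]:
        return sorted(e.id for e in self.edges.values() if e.is_half_edge)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for nid in self.nodes:
            g.add_node(("n", nid))
        for e in self.edges.values():
            g.add_node(("e", e.id))
            for nid in e.endpoints:
                g.add_edge(("e", e.id), ("n", nid))
        return g

    def is_acyclic(self) -> bool:
        return nx.is_forest(self.to_networkx())

    def observed_edges(self) -> Dict[str, Union[int, float, np.ndarray]]:
        return {
            e.id: e.observed_value
            for e in sorted(self.edges.values(), key=lambda e: e.id)
            if e.observed_value is not None
        }


@dataclasses.dataclass
class CompositeNode:
    """The result of closing a box around a connected node subset."""

    boundary: List[str]
    inner: Graph

    def __post_init__(self) -> None:
        for eid in self.boundary:
            e = self.inner.edges[eid]
            if len(e.endpoints) != 1:
                raise GraphSpecError(
                    f"boundary edge {eid!r} must have exactly one interior endpoint"
                )


# ----------------------------------------------------------------------------
# building from a model specification


def _parse_domain(d) -> Domain:
    if isinstance(d, (RealDomain, FiniteDomain)):
        return d
    if isinstance(d, dict):
        if d.get("type") == "real":
            return RealDomain(int(d.get("dim", 1)))
        if d.get("type") == "finite":
            return FiniteDomain(int(d["size"]))
    raise GraphSpecError(f"cannot parse domain {d!r}")


def _coerce_params(kind: str, params: dict) -> dict:
    out = dict(params or {})
    for key in ("table",):
        if key in out:
            t = np.asarray(out[key], dtype=float)
            if np.any(t < 0):
                raise GraphSpecError("probability tensors must be nonnegative")
            out[key] = t
    for key in ("a", "mean", "cov"):
        if key in out:
            out[key] = np.asarray(out[key], dtype=float)
    return out


def build_graph(spec: Union[dict, str]) -> Graph:
    """Build a graph from a structured model description.

    ``spec`` is a dict (or JSON string) with ``variables: [{name, domain,
    observed?}]`` and ``factors: [{name, kind, params?, variables}]``.
    Variables appearing in a single factor become half-edges.  Observed
    variables get an ``observation_terminal`` node attached.
    """
    if isinstance(spec, str):
        spec = json.loads(spec)
    g = Graph()
    for v in spec.get("variables", []):
        g.add_edge(VariableEdge(v["name"], v["name"], _parse_domain(v["domain"])))
    logical: List[LogicalFactor] = []
    for f in spec.get("factors", []):
        kind = f["kind"]
        arity = NODE_ARITY.get(kind, -1)
        if arity == -1:
            raise GraphSpecError(f"unknown factor kind {kind!r}")
        vnames = list(f.get("variables", []))
        for vn in vnames:
            if vn not in g.edges:
                raise GraphSpecError(f"factor {f['name']!r} uses unknown variable {vn!r}")
        params = _coerce_params(kind, f.get("params", {}))
        if arity is not None and len(vnames) != arity:
            raise GraphSpecError(
                f"factor {f['name']!r} kind {kind!r} needs {arity} variables, "
                f"got {len(vnames)}"
            )
        if kind in ("categorical_table", "custom_table"):
            shape = tuple(g.edges[v].domain.size for v in vnames)
            if params["table"].shape != shape:
                raise GraphSpecError(
                    f"factor {f['name']!r} table shape {params['table'].shape} "
                    f"does not match domains {shape}"
                )
            logical.append(LogicalFactor("categorical", tuple(vnames), params))
        elif kind == "gaussian_prior":
            logical.append(LogicalFactor("gaussian_prior", tuple(vnames), params))
        g.add_node(FactorNode(f["name"], kind, params, vnames))
    # observed variables: attach terminals, keep the delta-message mechanism
    for v in spec.get("variables", []):
        if "observed" in v and v["observed"] is not None:
            e = g.edges[v["name"]]
            val = v["observed"]
            if isinstance(e.domain, FiniteDomain):
                e.observed_value = int(val)
            else:
                e.observed_value = np.asarray(val, dtype=float)
            g.add_node(
                FactorNode(f"obs_{v['name']}", "observation_terminal", {}, [v["name"]])
            )
    g.logical_factors = logical or None
    return g


# ----------------------------------------------------------------------------
# equality-node normalization


def normalize_shared_variables(g: Graph) -> Graph:
    """Rewrite variables shared by >2 factors as equality-node chains.

    Each shared variable ``x`` keeps its first attachment; the remaining
    attachments move to auto-named copies ``x__1, x__2, ...`` joined by a
    chain of arity-3 equality nodes.  Marginals of original variables are
    unchanged.  Idempotent on already-normalized graphs.
    """
    g = g.copy()
    shared = sorted(e.id for e in g.edges.values() if len(e.endpoints) > 2)
    for eid in shared:
        edge = g.edges[eid]
        factors = list(edge.endpoints)  # f1 ... fk, k >= 3
        k = len(factors)
        edge.endpoints = [factors[0]]
        counter = itertools.count(1)

        def new_copy(attach_to: str) -> str:
            i = next(counter)
            cid = f"{edge.name}__{i}"
            if cid in g.edges:
                raise GraphSpecError(f"auxiliary id {cid!r} already exists")
            g.add_edge(
                VariableEdge(cid, cid, edge.domain, endpoints=[], origin=edge.name)
            )
            if attach_to:
                g.edges[cid].endpoints.append(attach_to)
                node = g.nodes[attach_to]
                node.interface = [cid if x == eid else x for x in node.interface]
                if node.kind == "observation_terminal":
                    # the delta message must follow its terminal to the copy
                    g.edges[cid].observed_value = edge.observed_value
                    edge.observed_value = None
            return cid

        carry = eid
        for j in range(k - 2):
            last = j == k - 3
            branch = new_copy(factors[j + 1])
            if last:
                nxt = new_copy(factors[j + 2])
            else:
                nxt = new_copy("")  # carry edge to the next equality node
            eq_id = f"eq_{edge.name}_{j + 1}"
            g.add_node(FactorNode(eq_id, "equality", {}, [carry, branch, nxt]))
            carry = nxt
    return g


# ----------------------------------------------------------------------------
# closing the box


def close_box(g: Graph, node_ids: Union[Set[str], Sequence[str]]) -> CompositeNode:
    """Close a box around ``node_ids``, yielding a composite node.

    The composite's outgoing message on each boundary edge equals the
    marginalization of the boxed factor product over fully-interior edges.
    """
    node_ids = set(node_ids)
    if not node_ids:
        raise GraphSpecError("cannot close a box around an empty node set")
    unknown = node_ids - set(g.nodes)
    if unknown:
        raise GraphSpecError(f"unknown node ids {sorted(unknown)}")
    sub = g.to_networkx().subgraph(
        [("n", n) for n in node_ids]
        + [("e", e.id) for e in g.edges.values() if set(e.endpoints) & node_ids]
    )
    if not nx.is_connected(sub):
        raise GraphSpecError("boxed node set must be connected")

    inner = Graph()
    boundary: List[str] = []
    for e in sorted(g.edges.values(), key=lambda e: e.id):
        inside = [n for n in e.endpoints if n in node_ids]
        if not inside:
            continue
        copy = dataclasses.replace(e, endpoints=list(inside))
        inner.edges[copy.id] = copy
        if len(inside) < len(e.endpoints) or (not e.endpoints):
            pass
        if len(inside) == 1 and len(e.endpoints) == 2:
            boundary.append(e.id)
            copy.observed_value = None  # evidence stays outside the box
    for nid in sorted(node_ids):
        n = g.nodes[nid]
        inner.nodes[nid] = dataclasses.replace(
            n, interface=list(n.interface), parameters=dict(n.parameters)
        )
    if not boundary:
        raise GraphSpecError(
            "box has no boundary edges; use the evidence operation for whole graphs"
        )
    return CompositeNode(boundary=boundary, inner=inner)


def boxed_graph(g: Graph, node_ids: Union[Set[str], Sequence[str]], box_id: str) -> Graph:
    """Replace ``node_ids`` in ``g`` by a single composite node."""
    comp = close_box(g, node_ids)
    node_ids = set(node_ids)
    out = Graph()
    for e in sorted(g.edges.values(), key=lambda e: e.id):
        keep_eps = [n for n in e.endpoints if n not in node_ids]
        if len(keep_eps) == len(e.endpoints) or e.id in comp.boundary:
            eps = keep_eps + ([box_id] if e.id in comp.boundary else [])
            out.edges[e.id] = dataclasses.replace(e, endpoints=eps)
    for nid, n in sorted(g.nodes.items()):
        if nid not in node_ids:
            out.nodes[nid] = dataclasses.replace(n, interface=list(n.interface))
    out.nodes[box_id] = FactorNode(
        box_id, "composite", {"composite": comp}, list(comp.boundary)
    )
    return out


# ----------------------------------------------------------------------------
# validation


def validate(g: Graph) -> List[str]:
    """Check graph invariants; return a list of human-readable violations."""
    violations: List[str] = []
    for e in sorted(g.edges.values(), key=lambda e: e.id):
        if len(e.endpoints) > 2:
            violations.append(
                f"edge {e.id!r} attaches to {len(e.endpoints)} factors "
                f"(at most 2 allowed; run normalize_shared_variables)"
            )
        if len(e.endpoints) == 0:
            violations.append(f"edge {e.id!r} is attached to no factor")
        for nid in e.endpoints:
            if nid not in g.nodes:
                violations.append(f"edge {e.id!r} references missing node {nid!r}")
            elif e.id not in g.nodes[nid].interface:
                violations.append(
                    f"incidence asymmetry: edge {e.id!r} lists node {nid!r} "
                    f"but not vice versa"
                )
        if e.observed_value is not None and isinstance(e.domain, FiniteDomain):
            if not (0 <= int(e.observed_value) < e.domain.size):
                violations.append(
                    f"edge {e.id!r} observed value {e.observed_value} outside domain"
                )
    for n in sorted(g.nodes.values(), key=lambda n: n.id):
        arity = NODE_ARITY.get(n.kind, -1)
        if arity == -1:
            violations.append(f"node {n.id!r} has unknown kind {n.kind!r}")
            continue
        if arity is not None and len(n.interface) != arity:
            violations.append(
                f"node {n.id!r} kind {n.kind!r} expects {arity} edges, "
                f"has {len(n.interface)}"
            )
        if n.kind in ("categorical_table", "custom_table"):
            t = n.parameters.get("table")
            if t is None:
                violations.append(f"node {n.id!r} lacks a probability table")
            elif np.any(np.asarray(t) < 0):
                violations.append(f"node {n.id!r} has negative table entries")
            elif t.ndim != len(n.interface):
                violations.append(
                    f"node {n.id!r} table order {t.ndim} != interface "
                    f"size {len(n.interface)}"
                )
        for eid in n.interface:
            if eid not in g.edges:
                violations.append(f"node {n.id!r} references missing edge {eid!r}")
            elif n.id not in g.edges[eid].endpoints:
                violations.append(
                    f"incidence asymmetry: node {n.id!r} lists edge {eid!r} "
                    f"but not vice versa"
                )
    return violations


# ----------------------------------------------------------------------------
# export


def graph_to_dict(g: Graph) -> dict:
    """Serializable description; round-trips through :func:`build_graph`."""

    def dom(d: Domain):
        if isinstance(d, FiniteDomain):
            return {"type": "finite", "size": d.size}
        return {"type": "real", "dim": d.dim}

    variables = []
    for e in sorted(g.edges.values(), key=lambda e: e.id):
        v = {"name": e.name, "domain": dom(e.domain)}
        if e.observed_value is not None:
            val = e.observed_value
            v["observed"] = val.tolist() if isinstance(val, np.ndarray) else val
        variables.append(v)
    factors = []
    for n in sorted(g.nodes.values(), key=lambda n: n.id):
        if n.kind == "observation_terminal":
            continue  # regenerated from the observed flag
        params = {}
        for k, v in n.parameters.items():
            params[k] = v.tolist() if isinstance(v, np.ndarray) else v
        factors.append(
            {"name": n.id, "kind": n.kind, "params": params, "variables": list(n.interface)}
        )
    return {"variables": variables, "factors": factors}


def to_dot(g: Graph) -> str:
    """DOT rendering with deterministic ordering; factors are boxes."""
    lines = ["graph ffg {", "  node [shape=box];"]
    for n in sorted(g.nodes.values(), key=lambda n: n.id):
        label = f"{n.id}\\n[{n.kind}]"
        lines.append(f'  "{n.id}" [label="{label}"];')
    for e in sorted(g.edges.values(), key=lambda e: e.id):
        style = " [style=bold]" if e.observed_value is not None else ""
        if len(e.endpoints) == 2:
            a, b = e.endpoints
            lines.append(f'  "{a}" -- "{b}" [label="{e.name}"]{style};')
        elif len(e.endpoints) == 1:
            stub = f"half_{e.id}"
            lines.append(f'  "{stub}" [shape=none, label=""];')
            lines.append(f'  "{e.endpoints[0]}" -- "{stub}" [label="{e.name}"]{style};')
    lines.append("}")
    return "\n".join(lines) + "\n"
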