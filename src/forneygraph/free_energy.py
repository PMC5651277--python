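"""Variational free energy: evaluation, decomposition, evidence, mean field.

The free energy of a proposal q against a model p with observations o is

    F[q] = E_q[log q(z)] - E_q[log p(z, o)]
         = -log p(o) + D(q(z) || p(z|o)),

an upper bound on the surprise -log p(o) with the KL divergence from q to
the exact posterior as the gap.

F is evaluated against the graph's *logical* factorization -- the
conditional densities of the model the graph represents (before equality
expansion and before deterministic-node decomposition) -- because expected
log-deltas under factorized proposals are ill-defined.  Builders record
logical factors; for graphs made only of table/prior nodes they are derived
automatically.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .beliefs import (
    CategoricalBelief,
    DegenerateEntropyError,
    GaussianBelief,
    PointMass,
)
from .graph import FiniteDomain, Graph, GraphSpecError, LogicalFactor
from .scheduling import ScheduleError, marginal_of, run, tree_schedule

__all__ = [
    "CategoricalBlock",
    "GaussianBlock",
    "ProposalSet",
    "FreeEnergyReport",
    "FreeEnergyError",
    "free_energy",
    "decompose",
    "evidence",
    "mean_field_step",
    "proposal_from_marginals",
]

_LOG_2PI = math.log(2.0 * math.pi)


class FreeEnergyError(GraphSpecError):
    pass


@dataclasses.dataclass
class CategoricalBlock:
    """A (possibly joint) categorical proposal factor over hidden variables."""

    variables: Tuple[str, ...]
    probs: np.ndarray  # axes follow `variables`; sums to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != len(self.variables):
            raise FreeEnergyError("block tensor order must match variable count")
        s = p.sum()
        if not np.isfinite(s) or s <= 0:
            raise FreeEnergyError("block is not normalizable")
        self.probs = p / s

    def marginal(self, variables: Sequence[str]) -> np.ndarray:
        keep = [self.variables.index(v) for v in variables]
        axes = tuple(i for i in range(self.probs.ndim) if i not in keep)
        m = self.probs.sum(axis=axes)
        return np.moveaxis(m, range(len(keep)), np.argsort(np.argsort(keep)))

    def entropy(self) -> float:
        p = self.probs.ravel()
        nz = p > 0
        return float(-np.sum(p[nz] * np.log(p[nz])))


@dataclasses.dataclass
class GaussianBlock:
    """A scalar Gaussian proposal factor q(x) = N(mean, var)."""

    variable: str
    mean: float
    var: float

    @property
    def variables(self) -> Tuple[str, ...]:
        return (self.variable,)

    def moments(self) -> Tuple[float, float]:
        return self.mean, self.mean**2 + self.var

    def entropy(self) -> float:
        if self.var <= 0:
            raise DegenerateEntropyError("point-mass proposal block")
        return 0.5 * (1.0 + _LOG_2PI + math.log(self.var))


Block = Union[CategoricalBlock, GaussianBlock]


@dataclasses.dataclass
class ProposalSet:
    """A mean-field partition of the hidden variables with one q per block."""

    blocks: List[Block]

    def block_of(self, var: str) -> Block:
        for b in self.blocks:
            if var in b.variables:
                return b
        raise FreeEnergyError(f"no proposal block covers variable {var!r}")

    def check_cover(self, hidden: Sequence[str]) -> None:
        covered: List[str] = []
        for b in self.blocks:
            covered.extend(b.variables)
        if sorted(covered) != sorted(set(covered)):
            raise FreeEnergyError("proposal blocks overlap")
        missing = set(hidden) - set(covered)
        extra = set(covered) - set(hidden)
        if missing or extra:
            raise FreeEnergyError(
                f"blocks must cover hidden variables exactly "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )

    def entropy(self) -> float:
        return sum(b.entropy() for b in self.blocks)

    def replace(self, index: int, block: Block) -> "ProposalSet":
        blocks = list(self.blocks)
        blocks[index] = block
        return ProposalSet(blocks)


@dataclasses.dataclass
class FreeEnergyReport:
    F: float
    surprise: Optional[float] = None
    divergence: Optional[float] = None
    trace: List[float] = dataclasses.field(default_factory=list)


# ----------------------------------------------------------------------------
# model-side helpers


def logical_factors_of(g: Graph) -> List[LogicalFactor]:
    if g.logical_factors is not None:
        return g.logical_factors
    out: List[LogicalFactor] = []
    for n in sorted(g.nodes.values(), key=lambda n: n.id):
        if n.kind in ("equality", "observation_terminal"):
            continue
        names = tuple(g.edges[e].origin for e in n.interface)
        if n.kind in ("categorical_table", "custom_table"):
            out.append(LogicalFactor("categorical", names, dict(n.parameters)))
        elif n.kind == "gaussian_prior":
            out.append(LogicalFactor("gaussian_prior", names, dict(n.parameters)))
        else:
            raise FreeEnergyError(
                f"node {n.id!r} ({n.kind}) has no logical density; "
                f"the builder must provide graph.logical_factors"
            )
    return out


def observed_values(g: Graph) -> Dict[str, Union[int, float]]:
    obs: Dict[str, Union[int, float]] = {}
    for eid, val in g.observed_edges().items():
        obs[g.edges[eid].origin] = val
    return obs


def hidden_variables(g: Graph) -> List[str]:
    obs = observed_values(g)
    names = {e.origin for e in g.edges.values()}
    return sorted(n for n in names if n not in obs)


# ----------------------------------------------------------------------------
# expected log factors


def _finite_size(g: Graph, name: str) -> int:
    for e in g.edges.values():
        if e.origin == name and isinstance(e.domain, FiniteDomain):
            return e.domain.size
    raise FreeEnergyError(f"{name!r} is not a finite-domain variable")


def _q_tensor(g: Graph, q: ProposalSet, obs: dict, variables: Sequence[str]) -> np.ndarray:
    """Joint proposal over a factor's variables (blocks independent)."""
    if len(set(variables)) != len(variables):
        raise FreeEnergyError("repeated variable in a factor")
    groups: List[Tuple[List[str], np.ndarray]] = []
    done: set = set()
    for v in variables:
        if v in done:
            continue  # already pulled in by a joint block
        if v in obs:
            size = _finite_size(g, v)
            one = np.zeros(size)
            one[int(obs[v])] = 1.0
            groups.append(([v], one))
            done.add(v)
            continue
        b = q.block_of(v)
        if not isinstance(b, CategoricalBlock):
            raise FreeEnergyError(f"variable {v!r} needs a categorical block")
        vs = [u for u in b.variables if u in variables and u not in done]
        groups.append((vs, b.marginal(vs)))
        done.update(vs)
    # outer product, then reorder axes to match `variables`
    order: List[str] = []
    tensor = np.array(1.0)
    for vs, m in groups:
        tensor = np.multiply.outer(tensor, m)
        order.extend(vs)
    tensor = tensor.reshape([1] * 0 + list(tensor.shape))
    perm = [order.index(v) for v in variables]
    return np.transpose(tensor, perm)


def _expected_log_categorical(g, q, obs, f: LogicalFactor) -> float:
    table = np.asarray(f.params["table"], dtype=float)
    qt = _q_tensor(g, q, obs, f.variables)
    with np.errstate(divide="ignore"):
        logt = np.log(table)
    vals = np.where(qt > 0, qt * logt, 0.0)
    if np.any(np.isnan(vals)) or np.any(np.isneginf(vals)):
        raise FreeEnergyError(
            f"proposal puts mass on a zero of factor over {f.variables}"
        )
    return float(vals.sum())


def _scalar_moments(q: ProposalSet, obs: dict, var: str) -> Tuple[float, float]:
    if var in obs:
        v = float(obs[var])
        return v, v * v
    b = q.block_of(var)
    if not isinstance(b, GaussianBlock):
        raise FreeEnergyError(f"variable {var!r} needs a Gaussian block")
    return b.moments()


def _expected_log_gaussian(q, obs, f: LogicalFactor) -> float:
    if f.kind == "gaussian_prior":
        (x,) = f.variables
        m = float(np.asarray(f.params["mean"]).reshape(()))
        v = float(np.asarray(f.params["cov"]).reshape(()))
        mq, x2 = _scalar_moments(q, obs, x)
        return -0.5 * (_LOG_2PI + math.log(v)) - (x2 - 2 * mq * m + m * m) / (2 * v)
    # linear_gaussian: child = gain * parent + N(0, noise)
    child, parent = f.params["child"], f.params["parent"]
    noise = float(f.params["noise_var"])
    if "gain_var" in f.params:
        mb, b2 = _scalar_moments(q, obs, f.params["gain_var"])
    else:
        mb = float(f.params["gain"])
        b2 = mb * mb
    mc, c2 = _scalar_moments(q, obs, child)
    mp, p2 = _scalar_moments(q, obs, parent)
    quad = c2 - 2 * mb * mc * mp + b2 * p2
    return -0.5 * (_LOG_2PI + math.log(noise)) - quad / (2 * noise)


def expected_log_factor(g, q, obs, f: LogicalFactor) -> float:
    if f.kind == "categorical":
        return _expected_log_categorical(g, q, obs, f)
    if f.kind in ("gaussian_prior", "linear_gaussian"):
        return _expected_log_gaussian(q, obs, f)
    raise FreeEnergyError(f"unknown logical factor kind {f.kind!r}")


# ----------------------------------------------------------------------------
# the functional


def free_energy(g: Graph, q: ProposalSet) -> FreeEnergyReport:
    """Evaluate F[q] = E_q[log q] - E_q[log p(z, o)] factor by factor."""
    obs = observed_values(g)
    q.check_cover(hidden_variables(g))
    energy = sum(expected_log_factor(g, q, obs, f) for f in logical_factors_of(g))
    return FreeEnergyReport(F=-q.entropy() - energy)


def decompose(report: FreeEnergyReport, log_evidence: float) -> FreeEnergyReport:
    """Split F into surprise (-log evidence) plus KL divergence."""
    surprise = -log_evidence
    divergence = report.F - surprise
    if divergence < -1e-9:
        raise FreeEnergyError(
            f"negative divergence {divergence:.3e}: inconsistent q or evidence"
        )
    return dataclasses.replace(
        report, surprise=surprise, divergence=max(divergence, 0.0)
    )


def evidence(g: Graph) -> float:
    """log p(o) by closing the box around the entire (acyclic) graph.

    The accumulated message scales on any edge of a connected component give
    that component's evidence; components add.
    """
    if not g.is_acyclic():
        raise FreeEnergyError("evidence by closing-the-box needs an acyclic graph")
    sched = tree_schedule(g)
    from .scheduling import MessageState, execute_step

    state = MessageState()
    for step in sched.steps:
        execute_step(g, state, step)
    import networkx as nx

    nxg = g.to_networkx()
    total = 0.0
    for comp in nx.connected_components(nxg):
        eids = sorted(x[1] for x in comp if x[0] == "e")
        if not eids:
            continue
        total += marginal_of(g, state, eids[0]).log_normalizer
    return total


# ----------------------------------------------------------------------------
# mean-field coordinate updates


def mean_field_step(g: Graph, q: ProposalSet, block: int) -> ProposalSet:
    """Coordinate update: q_i proportional to exp(E_{q_{j != i}}[log p(z, o)]).

    All other blocks are held fixed; the free energy cannot increase.
    """
    obs = observed_values(g)
    b = q.blocks[block]
    factors = [f for f in logical_factors_of(g)
               if set(f.variables) & set(b.variables)]
    if isinstance(b, CategoricalBlock):
        shape = tuple(_finite_size(g, v) for v in b.variables)
        acc = np.zeros(shape)
        for f in factors:
            table = np.asarray(f.params["table"], dtype=float)
            with np.errstate(divide="ignore"):
                logt = np.log(table)
            in_block = [v for v in f.variables if v in b.variables]
            outside = [v for v in f.variables if v not in b.variables]
            # reorder factor axes: outside variables first, block variables last
            perm = [f.variables.index(v) for v in outside + in_block]
            logt_p = np.transpose(logt, perm)
            if outside:
                qt = _q_tensor(g, q, obs, outside)
                qt_e = qt.reshape(qt.shape + (1,) * len(in_block))
                with np.errstate(invalid="ignore"):
                    vals = np.where(qt_e > 0, qt_e * logt_p, 0.0)
                val = vals.sum(axis=tuple(range(len(outside))))
            else:
                val = logt_p
            # broadcast over block variables absent from this factor
            block_axes = [in_block.index(v) if v in in_block else None
                          for v in b.variables]
            src = np.transpose(val, [in_block.index(v) for v in b.variables
                                     if v in in_block])
            full_shape = [shape[i] if block_axes[i] is not None else 1
                          for i in range(len(b.variables))]
            acc = acc + src.reshape(full_shape)
        lw = acc - acc[np.isfinite(acc)].max() if np.any(np.isfinite(acc)) else acc
        probs = np.exp(lw)
        total = probs.sum()
        if not np.isfinite(total) or total <= 0:
            raise FreeEnergyError("mean-field update is not normalizable")
        return q.replace(block, CategoricalBlock(b.variables, probs / total))

    # Gaussian scalar block
    var = b.variable
    W = 0.0
    h = 0.0
    for f in factors:
        if f.kind == "gaussian_prior":
            m = float(np.asarray(f.params["mean"]).reshape(()))
            v = float(np.asarray(f.params["cov"]).reshape(()))
            W += 1.0 / v
            h += m / v
        elif f.kind == "linear_gaussian":
            noise = float(f.params["noise_var"])
            child, parent = f.params["child"], f.params["parent"]
            gain_var = f.params.get("gain_var")
            if gain_var is not None:
                mb, b2 = _scalar_moments(q, obs, gain_var)
            else:
                mb = float(f.params["gain"])
                b2 = mb * mb
            if var == child:
                mp, _ = _scalar_moments(q, obs, parent)
                W += 1.0 / noise
                h += mb * mp / noise
            elif var == parent:
                mc, _ = _scalar_moments(q, obs, child)
                W += b2 / noise
                h += mb * mc / noise
            elif var == gain_var:
                mp, p2 = _scalar_moments(q, obs, parent)
                mc, _ = _scalar_moments(q, obs, child)
                W += p2 / noise
                h += mp * mc / noise
        else:
            raise FreeEnergyError("Gaussian block touched by a categorical factor")
    if W <= 0:
        raise FreeEnergyError("mean-field update is not normalizable")
    return q.replace(block, GaussianBlock(var, h / W, 1.0 / W))


def proposal_from_marginals(g: Graph, marginals) -> ProposalSet:
    """Naive mean-field proposal from per-edge marginals (one block per
    original hidden variable; auxiliary equality copies are skipped)."""
    hidden = set(hidden_variables(g))
    blocks: List[Block] = []
    seen: set = set()
    for eid in sorted(marginals):
        e = g.edges[eid]
        if e.origin in seen or e.origin not in hidden:
            continue
        bel = marginals[eid].belief
        if isinstance(bel, CategoricalBelief):
            blocks.append(CategoricalBlock((e.origin,), bel.probs))
        elif isinstance(bel, GaussianBelief):
            blocks.append(GaussianBlock(e.origin, bel.mean_scalar, bel.cov_scalar))
        elif isinstance(bel, PointMass) and bel.is_discrete:
            size = e.domain.size
            p = np.zeros(size)
            p[int(bel.value)] = 1.0
            blocks.append(CategoricalBlock((e.origin,), p))
        else:
            continue
        seen.add(e.origin)
    return ProposalSet(blocks)
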