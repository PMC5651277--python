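"""Node-local message computations.

Three rule families: the generic sum-product rule (exact tensor contraction
for table nodes, closed Gaussian forms for the standard linear nodes), the
terminal/observation messages, and the variational rule (exponentiated
expected log-factor under incoming marginals).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Optional

import numpy as np
from scipy import integrate
from scipy.special import logsumexp

from .beliefs import (
    VACUOUS,
    Belief,
    BeliefError,
    CategoricalBelief,
    GaussianBelief,
    Marginal,
    Message,
    PointMass,
    SupportMismatchError,
    Vacuous,
)
from .graph import FiniteDomain, FactorNode, Graph, VariableEdge

__all__ = [
    "RuleResult",
    "RuleError",
    "sum_product",
    "gaussian_rule",
    "terminal_message",
    "observation_message",
    "variational",
    "gain_variational",
    "linear_gaussian_variational",
    "quadrature_message",
]


class RuleError(BeliefError):
    """Raised when a rule cannot be applied to the given inputs."""


@dataclasses.dataclass
class RuleResult:
    message: Message
    rule_tag: str
    notes: str = ""


def _result(g: Graph, node_id: str, target: str, belief: Belief, tag: str, notes=""):
    toward = g.other_endpoint(target, node_id)
    return RuleResult(Message(target, toward, belief), tag, notes)


# ----------------------------------------------------------------------------
# elementary products (unnormalized, scale preserved)


def unnormalized_product(a: Belief, b: Belief) -> Belief:
    if isinstance(a, Vacuous):
        return b
    if isinstance(b, Vacuous):
        return a
    if isinstance(a, PointMass) and isinstance(b, PointMass):
        raise RuleError("product of two point masses on one edge")
    if isinstance(a, PointMass) or isinstance(b, PointMass):
        pm, other = (a, b) if isinstance(a, PointMass) else (b, a)
        if isinstance(other, GaussianBelief):
            return PointMass(pm.value, pm.log_scale + other.logpdf_unnorm(pm.value))
        if isinstance(other, CategoricalBelief):
            lw = float(other.log_weights[int(pm.value)])
            return PointMass(pm.value, pm.log_scale + lw)
        raise SupportMismatchError("point mass with incompatible belief")
    if isinstance(a, GaussianBelief) and isinstance(b, GaussianBelief):
        return a.multiply(b)
    if isinstance(a, CategoricalBelief) and isinstance(b, CategoricalBelief):
        return a.multiply(b)
    raise SupportMismatchError(f"cannot multiply {a!r} with {b!r}")


# ----------------------------------------------------------------------------
# terminals


def observation_message(edge: VariableEdge, from_node: Optional[str] = None
                        ) -> RuleResult:
    """Delta message for an observed edge, vacuous for an unobserved one.

    The message points away from ``from_node`` (the terminal emitting it).
    """
    if edge.observed_value is None:
        belief: Belief = VACUOUS
    elif isinstance(edge.domain, FiniteDomain):
        belief = PointMass(int(edge.observed_value))
    else:
        belief = PointMass(np.asarray(edge.observed_value, dtype=float))
    others = [n for n in edge.endpoints if n != from_node]
    toward = others[0] if others else None
    return RuleResult(Message(edge.id, toward, belief), "observation")


def terminal_message(node: FactorNode, g: Graph) -> RuleResult:
    """Closing the box around a terminal node yields the factor itself."""
    if len(node.interface) != 1:
        raise RuleError(f"terminal rule needs arity 1, node {node.id!r} has "
                        f"{len(node.interface)}")
    target = node.interface[0]
    if node.kind == "gaussian_prior":
        belief: Belief = GaussianBelief.from_moment(
            node.parameters["mean"], node.parameters["cov"]
        )
    elif node.kind in ("categorical_table", "custom_table"):
        belief = CategoricalBelief(node.parameters["table"])
    elif node.kind == "observation_terminal":
        return observation_message(g.edges[target], from_node=node.id)
    else:
        raise RuleError(f"no terminal rule for kind {node.kind!r}")
    return _result(g, node.id, target, belief, "terminal")


# ----------------------------------------------------------------------------
# Gaussian closed forms for the standard linear nodes


def _negate(b: Belief) -> Belief:
    if isinstance(b, Vacuous):
        return b
    if isinstance(b, PointMass):
        return PointMass(-np.asarray(b.value, dtype=float), b.log_scale)
    if isinstance(b, GaussianBelief):
        return GaussianBelief(b.W, -b.h, b.g)
    raise RuleError("cannot negate a categorical belief")


def _convolve(a: Belief, b: Belief) -> Belief:
    """Belief of the sum of two independent variables."""
    if isinstance(a, Vacuous) or isinstance(b, Vacuous):
        return VACUOUS
    if isinstance(a, PointMass) and isinstance(b, PointMass):
        return PointMass(
            np.asarray(a.value, float) + np.asarray(b.value, float),
            a.log_scale + b.log_scale,
        )
    if isinstance(a, PointMass) or isinstance(b, PointMass):
        pm, other = (a, b) if isinstance(a, PointMass) else (b, a)
        if not isinstance(other, GaussianBelief):
            raise RuleError("convolution needs Gaussian or point-mass inputs")
        shifted = other.shift(np.asarray(pm.value, float))
        return GaussianBelief.from_moment(
            shifted.mean, shifted.cov, shifted.log_integral + pm.log_scale
        )
    if isinstance(a, GaussianBelief) and isinstance(b, GaussianBelief):
        return a.convolve(b)
    raise RuleError("convolution needs Gaussian or point-mass inputs")


def gaussian_rule(kind: str, inbound: Dict[str, Belief], params: dict) -> Belief:
    """Closed-form message for the standard linear-Gaussian nodes.

    ``kind`` is one of ``addition`` (roles x, y -> z: means and variances
    add), ``subtraction`` (roles z, x -> y: my = mz - mx, vy = vz + vx),
    ``gain_forward`` (y = a x: my = a mx, vy = a^2 vx), ``gain_backward``
    (mx = y/a, vx = vy / a^2, via the canonical form for matrix gains),
    ``equality`` (precision-weighted fusion) and ``gaussian_prior``.
    """
    if kind == "addition":
        return _convolve(inbound["x"], inbound["y"])
    if kind == "subtraction":
        return _convolve(inbound["z"], _negate(inbound["x"]))
    if kind == "gain_forward":
        a = np.atleast_2d(np.asarray(params["a"], dtype=float))
        b = inbound["x"]
        if isinstance(b, Vacuous):
            return VACUOUS
        if isinstance(b, PointMass):
            return PointMass((a @ b.vector()), b.log_scale)
        try:
            return b.pushforward(a)
        except np.linalg.LinAlgError:
            # rank-deficient gain collapses the belief to a point mass
            return PointMass(a @ b.mean, b.log_integral)
    if kind == "gain_backward":
        a = np.atleast_2d(np.asarray(params["a"], dtype=float))
        b = inbound["y"]
        if isinstance(b, Vacuous):
            return VACUOUS
        if isinstance(b, PointMass):
            if a.shape[0] != a.shape[1]:
                raise RuleError("point mass cannot be pulled through a non-square gain")
            sign, logdet = np.linalg.slogdet(a)
            if sign == 0:
                raise RuleError("gain_backward with a singular (zero) gain")
            return PointMass(np.linalg.solve(a, b.vector()), b.log_scale - logdet)
        return b.pullback(a)
    if kind == "equality":
        return unnormalized_product(inbound["x"], inbound["y"])
    if kind == "gaussian_prior":
        return GaussianBelief.from_moment(params["mean"], params["cov"])
    raise RuleError(f"no Gaussian rule for kind {kind!r}")


# ----------------------------------------------------------------------------
# generic sum-product


def _table_log(node: FactorNode) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(np.asarray(node.parameters["table"], dtype=float))


def _log_vector(b: Belief, size: int) -> np.ndarray:
    if isinstance(b, Vacuous):
        return np.zeros(size)
    if isinstance(b, CategoricalBelief):
        if b.size != size:
            raise SupportMismatchError("alphabet size mismatch in contraction")
        return b.log_weights
    if isinstance(b, PointMass):
        v = np.full(size, -np.inf)
        v[int(b.value)] = b.log_scale
        return v
    raise SupportMismatchError("table node received a continuous belief")


def sum_product(
    node: FactorNode,
    inbound: Dict[str, Belief],
    target: str,
    g: Graph,
) -> RuleResult:
    """Generic sum-product update: product of all incoming messages with the
    factor, marginalized over the incoming-edge variables."""
    if target not in node.interface:
        raise RuleError(f"edge {target!r} is not on node {node.id!r}")
    if len(node.interface) == 1 and node.kind != "composite":
        return dataclasses.replace(terminal_message(node, g), rule_tag="sum_product")

    missing = [e for e in node.interface if e != target and e not in inbound]
    if missing:
        raise RuleError(f"node {node.id!r}: missing inbound messages on {missing}")

    if node.kind in ("categorical_table", "custom_table"):
        logt = _table_log(node)
        axes = {eid: i for i, eid in enumerate(node.interface)}
        acc = logt
        for eid in node.interface:
            if eid == target:
                continue
            lv = _log_vector(inbound[eid], logt.shape[axes[eid]])
            shape = [1] * logt.ndim
            shape[axes[eid]] = lv.size
            acc = acc + lv.reshape(shape)
        other_axes = tuple(i for eid, i in axes.items() if eid != target)
        with np.errstate(invalid="ignore"):
            lw = logsumexp(acc, axis=other_axes)
        belief: Belief = CategoricalBelief(log_weights=np.atleast_1d(lw))
        return _result(g, node.id, target, belief, "sum_product")

    if node.kind == "equality":
        others = [e for e in node.interface if e != target]
        if len(others) != 2:
            raise RuleError("equality node must have arity 3")
        belief = unnormalized_product(inbound[others[0]], inbound[others[1]])
        return _result(g, node.id, target, belief, "sum_product")

    if node.kind in ("addition", "subtraction"):
        # interface order is (x, y, z) with factor delta(x + y - z)
        x_id, y_id, z_id = node.interface
        if target == z_id:
            belief = _convolve(inbound[x_id], inbound[y_id])
        elif target == y_id:
            belief = _convolve(inbound[z_id], _negate(inbound[x_id]))
        else:
            belief = _convolve(inbound[z_id], _negate(inbound[y_id]))
        return _result(g, node.id, target, belief, "sum_product")

    if node.kind == "gain":
        x_id, y_id = node.interface  # y = a x
        if target == y_id:
            belief = gaussian_rule("gain_forward", {"x": inbound[x_id]}, node.parameters)
        else:
            belief = gaussian_rule("gain_backward", {"y": inbound[y_id]}, node.parameters)
        return _result(g, node.id, target, belief, "sum_product")

    if node.kind == "composite":
        from .scheduling import composite_message  # local import, avoids a cycle

        belief = composite_message(node.parameters["composite"], inbound, target)
        return _result(g, node.id, target, belief, "sum_product")

    raise RuleError(f"no sum-product rule for kind {node.kind!r}")


# ----------------------------------------------------------------------------
# variational rule


def _probs(b: Belief, size: int) -> np.ndarray:
    if isinstance(b, PointMass):
        p = np.zeros(size)
        p[int(b.value)] = 1.0
        return p
    if isinstance(b, CategoricalBelief):
        return b.probs
    if isinstance(b, Vacuous):
        return np.full(size, 1.0 / size)
    raise SupportMismatchError("need a discrete marginal")


def variational(
    node: FactorNode,
    inbound_marginals: Dict[str, Belief],
    target: str,
    g: Graph,
) -> RuleResult:
    """Variational message: nu(target) proportional to exp E_q[log factor].

    Expectations are taken under the *marginals* on the other interface
    edges.  At equality and prior nodes this coincides with sum-product.
    """
    if node.kind in ("equality", "gaussian_prior", "observation_terminal"):
        res = sum_product(node, inbound_marginals, target, g)
        return dataclasses.replace(res, rule_tag="variational")
    if node.kind in ("categorical_table", "custom_table"):
        logt = _table_log(node)
        axes = {eid: i for i, eid in enumerate(node.interface)}
        # E[log f] as a function of the target variable: weight log-table by
        # the product of marginals on the other axes and sum them out.
        acc = logt
        for eid in node.interface:
            if eid == target:
                continue
            p = _probs(inbound_marginals[eid], logt.shape[axes[eid]])
            shape = [1] * acc.ndim
            shape[axes[eid]] = p.size
            contrib = np.where(
                p.reshape(shape) > 0, p.reshape(shape) * acc, 0.0
            )
            acc = contrib.sum(axis=axes[eid], keepdims=True)
        lw = np.squeeze(acc)
        if not np.all(np.isfinite(lw[np.isfinite(lw)])):  # pragma: no cover
            raise RuleError("expected log-factor is not finite")
        belief: Belief = CategoricalBelief(log_weights=np.atleast_1d(lw))
        return _result(g, node.id, target, belief, "variational")
    raise RuleError(f"no variational rule for kind {node.kind!r}")


def _moments(q: Belief) -> tuple:
    """(mean, second moment) of a scalar marginal."""
    if isinstance(q, PointMass):
        m = float(np.asarray(q.value, float).reshape(()))
        return m, m * m
    if isinstance(q, GaussianBelief):
        m, v = q.mean_scalar, q.cov_scalar
        return m, m * m + v
    raise SupportMismatchError("need a scalar Gaussian or point-mass marginal")


def gain_variational(q_prev: Marginal, q_curr: Marginal, var_s: float) -> RuleResult:
    """Gaussian variational message over the transition gain beta.

    From E_q[log N(s_t | beta s_{t-1}, var_s)], quadratic in beta:
    precision E[s_{t-1}^2]/var_s and mean m_{t-1} m_t / E[s_{t-1}^2]
    (mean-field cross moment E[s_{t-1} s_t] = m_{t-1} m_t).
    """
    if var_s <= 0:
        raise RuleError("process-noise variance must be positive")
    m_prev, s2_prev = _moments(q_prev.belief)
    m_curr, _ = _moments(q_curr.belief)
    if s2_prev == 0.0:
        return RuleResult(Message(q_prev.edge_id, None, VACUOUS), "variational",
                          "uninformative direction: E[s_prev^2] = 0")
    W = s2_prev / var_s
    h = (m_prev * m_curr) / var_s
    return RuleResult(
        Message("beta", None, GaussianBelief(np.array([[W]]), np.array([h]))),
        "variational",
    )


def linear_gaussian_variational(
    target_role: str,
    q_parent: Optional[Belief],
    q_child: Optional[Belief],
    gain,
    noise_var: float,
    q_gain: Optional[Belief] = None,
) -> GaussianBelief:
    """Variational message of the factor N(child | gain * parent, noise_var).

    ``target_role`` is ``"child"`` or ``"parent"``; the gain is either a
    fixed scalar or carries a Gaussian marginal ``q_gain``.
    """
    if q_gain is not None:
        mb, b2 = _moments(q_gain)
    else:
        mb, b2 = float(gain), float(gain) ** 2
    if target_role == "child":
        mp, _ = _moments(q_parent)
        W = 1.0 / noise_var
        h = mb * mp / noise_var
    elif target_role == "parent":
        mc, _ = _moments(q_child)
        W = b2 / noise_var
        h = mb * mc / noise_var
    else:
        raise RuleError(f"unknown target role {target_role!r}")
    return GaussianBelief(np.array([[W]]), np.array([h]))


# ----------------------------------------------------------------------------
# quadrature fallback (oracle duty, not the production path)


def quadrature_message(
    factor, inbound: Dict[str, Belief], target: str, variables, limit: float = 30.0
) -> GaussianBelief:
    """Numerically integrate a scalar factor against incoming beliefs.

    ``factor`` is a callable of keyword scalars; ``variables`` the ordered
    variable names; incoming beliefs on the non-target variables are densities.
    Returns a moment-matched Gaussian with the exact mass as scale.
    """

    def density(b: Belief, x: float) -> float:
        if isinstance(b, Vacuous):
            return 1.0
        if isinstance(b, GaussianBelief):
            return math.exp(b.logpdf_unnorm(x))
        raise RuleError("quadrature supports scalar Gaussian/vacuous inputs")

    others = [v for v in variables if v != target]

    def integrand_factory(power: int):
        def outer(y: float) -> float:
            def inner(*xs: float) -> float:
                kwargs = dict(zip(others, xs))
                kwargs[target] = y
                val = factor(**kwargs)
                for v, x in zip(others, xs):
                    val *= density(inbound[v], x)
                return val

            if not others:
                return (y ** power) * inner()
            if len(others) == 1:
                val, _ = integrate.quad(inner, -limit, limit, limit=200)
            else:
                val, _ = integrate.dblquad(
                    lambda a, b: inner(b, a), -limit, limit, -limit, limit
                )
            return (y ** power) * val

        return outer

    z0, _ = integrate.quad(integrand_factory(0), -limit, limit, limit=200)
    z1, _ = integrate.quad(integrand_factory(1), -limit, limit, limit=200)
    z2, _ = integrate.quad(integrand_factory(2), -limit, limit, limit=200)
    if z0 <= 0:
        raise RuleError("non-integrable product in quadrature rule")
    mean = z1 / z0
    var = z2 / z0 - mean * mean
    return GaussianBelief.from_moment(mean, var, math.log(z0))
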