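"""Independent brute-force references for the message-passing engine.

Nothing here shares rule code with the engine: discrete graphs are summed
exhaustively, linear-Gaussian models are solved by assembling the joint
precision matrix, and Kalman filtering follows the textbook predict/update
recursion.  Disagreement with the engine beyond tolerance is a bug.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .graph import FiniteDomain, Graph, GraphSpecError, RealDomain

__all__ = [
    "ExactResult",
    "StateSpaceTooLarge",
    "enumerate_exact",
    "gaussian_exact",
    "kalman_reference",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: refusal threshold for exhaustive enumeration
MAX_CONFIGURATIONS = 10**7


class StateSpaceTooLarge(GraphSpecError):
    def __init__(self, count: float):
        self.count = count
        super().__init__(f"state space has {count:.3g} configurations (> {MAX_CONFIGURATIONS:g})")


@dataclasses.dataclass
class ExactResult:
    """Exact per-variable marginals (keyed by original variable name and by
    edge id) and the log evidence."""

    marginals: Dict[str, np.ndarray]
    log_evidence: float


# ----------------------------------------------------------------------------
# exhaustive enumeration for discrete graphs


def enumerate_exact(g: Graph, axis_order: Optional[Sequence[str]] = None) -> ExactResult:
    """Marginals and evidence by full summation over every configuration.

    Equality nodes are honored by identifying auxiliary copies with their
    original variable; observed variables are clamped.  Refuses state spaces
    above ``MAX_CONFIGURATIONS``.  ``axis_order`` permutes the summation
    order (the result is invariant; used as a self-check).
    """
    obs: Dict[str, int] = {}
    sizes: Dict[str, int] = {}
    for e in g.edges.values():
        if not isinstance(e.domain, FiniteDomain):
            raise GraphSpecError("enumeration needs finite domains everywhere")
        name = e.origin
        sizes.setdefault(name, e.domain.size)
        if sizes[name] != e.domain.size:
            raise GraphSpecError(f"inconsistent domain sizes for {name!r}")
        if e.observed_value is not None:
            obs[name] = int(e.observed_value)

    hidden = sorted(n for n in sizes if n not in obs)
    if axis_order is not None:
        if sorted(axis_order) != hidden:
            raise GraphSpecError("axis_order must permute the hidden variables")
        hidden = list(axis_order)
    count = float(np.prod([sizes[v] for v in hidden], dtype=float)) if hidden else 1.0
    if count > MAX_CONFIGURATIONS:
        raise StateSpaceTooLarge(count)

    shape = tuple(sizes[v] for v in hidden)
    joint_log = np.zeros(shape)
    for node in sorted(g.nodes.values(), key=lambda n: n.id):
        if node.kind in ("equality", "observation_terminal"):
            continue
        if node.kind not in ("categorical_table", "custom_table"):
            raise GraphSpecError(f"enumeration cannot evaluate kind {node.kind!r}")
        table = np.asarray(node.parameters["table"], dtype=float)
        with np.errstate(divide="ignore"):
            logt = np.log(table)
        names = [g.edges[e].origin for e in node.interface]
        if len(set(names)) != len(names):
            raise GraphSpecError(f"factor {node.id!r} repeats a variable")
        # clamp observed axes
        for ax in reversed(range(len(names))):
            if names[ax] in obs:
                logt = np.take(logt, obs[names[ax]], axis=ax)
                del names[ax]
        if names:
            perm = sorted(range(len(names)), key=lambda i: hidden.index(names[i]))
            logt = np.transpose(logt, perm)
            names = [names[i] for i in perm]
            expand = [sizes[v] if v in names else 1 for v in hidden]
            joint_log = joint_log + logt.reshape(expand)
        else:
            joint_log = joint_log + float(logt)

    log_Z = float(logsumexp(joint_log)) if joint_log.size else float(joint_log)
    marginals: Dict[str, np.ndarray] = {}
    for i, v in enumerate(hidden):
        axes = tuple(j for j in range(len(hidden)) if j != i)
        lm = logsumexp(joint_log, axis=axes) if axes else joint_log
        marginals[v] = np.exp(lm - log_Z)
    for v, idx in obs.items():
        one = np.zeros(sizes[v])
        one[idx] = 1.0
        marginals[v] = one
    # also expose per-edge marginals (auxiliary copies share the original's)
    for e in g.edges.values():
        if e.id not in marginals:
            marginals[e.id] = marginals[e.origin]
    return ExactResult(marginals=marginals, log_evidence=log_Z)


# ----------------------------------------------------------------------------
# joint-Gaussian linear algebra for linear-Gaussian models


def _var_layout(g: Graph):
    model_vars = set()
    for f in g.logical_factors or []:
        model_vars.update(f.variables)
    dims: Dict[str, int] = {}
    obs: Dict[str, np.ndarray] = {}
    for e in sorted(g.edges.values(), key=lambda e: e.id):
        if e.origin not in model_vars:
            continue  # auxiliary variable of the primitive decomposition
        if not isinstance(e.domain, RealDomain):
            raise GraphSpecError("gaussian_exact needs real domains everywhere")
        dims.setdefault(e.origin, e.domain.dim)
        if e.observed_value is not None:
            obs[e.origin] = np.atleast_1d(np.asarray(e.observed_value, dtype=float))
    names = sorted(dims)
    offsets: Dict[str, int] = {}
    pos = 0
    for n in names:
        offsets[n] = pos
        pos += dims[n]
    return names, dims, offsets, pos, obs


def gaussian_exact(g: Graph) -> ExactResult:
    """Posterior marginals and evidence by assembling the joint precision.

    Requires the graph's logical factorization (gaussian priors and linear-
    Gaussian conditionals); conditions on observed variables exactly.
    Marginal entries are (mean, cov) pairs keyed by variable name.
    """
    if g.logical_factors is None:
        raise GraphSpecError("gaussian_exact needs graph.logical_factors")
    names, dims, offsets, total, obs = _var_layout(g)
    J = np.zeros((total, total))
    h = np.zeros(total)
    g0 = 0.0

    def sl(name: str) -> slice:
        return slice(offsets[name], offsets[name] + dims[name])

    for f in g.logical_factors:
        if f.kind == "gaussian_prior":
            (x,) = f.variables
            m = np.atleast_1d(np.asarray(f.params["mean"], float))
            V = np.atleast_2d(np.asarray(f.params["cov"], float))
            W = np.linalg.inv(V)
            J[sl(x), sl(x)] += W
            h[sl(x)] += W @ m
            _, ld = np.linalg.slogdet(V)
            g0 += -0.5 * (m @ W @ m + dims[x] * _LOG_2PI + ld)
        elif f.kind == "linear_gaussian":
            child, parent = f.params["child"], f.params["parent"]
            if "gain_var" in f.params:
                raise GraphSpecError("gaussian_exact needs fixed gains")
            B = np.atleast_2d(np.asarray(f.params["gain"], float))
            Q = np.atleast_2d(np.asarray(f.params["noise_var"], float))
            Wn = np.linalg.inv(Q)
            J[sl(child), sl(child)] += Wn
            J[sl(parent), sl(parent)] += B.T @ Wn @ B
            J[sl(child), sl(parent)] += -Wn @ B
            J[sl(parent), sl(child)] += -B.T @ Wn
            _, ld = np.linalg.slogdet(Q)
            g0 += -0.5 * (dims[child] * _LOG_2PI + ld)
        else:
            raise GraphSpecError(f"gaussian_exact cannot handle {f.kind!r}")

    hidden = [n for n in names if n not in obs]
    hid_idx = np.concatenate([np.arange(offsets[n], offsets[n] + dims[n])
                              for n in hidden]) if hidden else np.array([], int)
    obs_idx = np.concatenate([np.arange(offsets[n], offsets[n] + dims[n])
                              for n in names if n in obs]) if obs else np.array([], int)
    y = np.concatenate([obs[n] for n in names if n in obs]) if obs else np.array([])

    Jzz = J[np.ix_(hid_idx, hid_idx)]
    if obs_idx.size:
        Jzo = J[np.ix_(hid_idx, obs_idx)]
        Joo = J[np.ix_(obs_idx, obs_idx)]
        l = h[hid_idx] - Jzo @ y
        const = g0 + float(h[obs_idx] @ y) - 0.5 * float(y @ Joo @ y)
    else:
        l = h[hid_idx]
        const = g0

    if hid_idx.size:
        L = np.linalg.cholesky(Jzz)
        mean = np.linalg.solve(Jzz, l)
        cov = np.linalg.inv(Jzz)
        logdet_J = 2.0 * np.sum(np.log(np.diag(L)))
        log_Z = const + 0.5 * float(l @ mean) + 0.5 * (
            hid_idx.size * _LOG_2PI - logdet_J
        )
    else:
        mean = np.array([])
        cov = np.zeros((0, 0))
        log_Z = const

    marginals: Dict[str, tuple] = {}
    pos = 0
    for n in hidden:
        d = dims[n]
        marginals[n] = (mean[pos:pos + d].copy(),
                        cov[pos:pos + d, pos:pos + d].copy())
        pos += d
    for n in names:
        if n in obs:
            marginals[n] = (obs[n], np.zeros((dims[n], dims[n])))
    return ExactResult(marginals=marginals, log_evidence=float(log_Z))


# ----------------------------------------------------------------------------
# classical Kalman recursion


@dataclasses.dataclass
class KalmanResult:
    means: List[np.ndarray]
    covs: List[np.ndarray]
    log_evidence: float


def kalman_reference(spec, observations: Sequence) -> KalmanResult:
    """Textbook Kalman filter (predict/update) with the prediction-error
    log-evidence decomposition.  ``spec`` provides A, B, var_s, var_o, m0, v0.
    Observations may contain None (no update that step)."""
    A = np.atleast_2d(np.asarray(spec.A, float))
    B = np.atleast_2d(np.asarray(spec.B, float))
    Q = np.atleast_2d(np.asarray(spec.var_s, float))
    R = np.atleast_2d(np.asarray(spec.var_o, float))
    m = np.atleast_1d(np.asarray(spec.m0, float))
    P = np.atleast_2d(np.asarray(spec.v0, float))
    if np.any(np.linalg.eigvalsh(Q) < -1e-12) or np.any(np.linalg.eigvalsh(R) < -1e-12):
        raise GraphSpecError("noise covariances must be PSD")
    means, covs = [], []
    loglik = 0.0
    d_obs = A.shape[0]
    for y in observations:
        m = B @ m
        P = B @ P @ B.T + Q
        if y is not None:
            y = np.atleast_1d(np.asarray(y, float))
            S = A @ P @ A.T + R
            resid = y - A @ m
            K = P @ A.T @ np.linalg.inv(S)
            m = m + K @ resid
            P = (np.eye(P.shape[0]) - K @ A) @ P
            _, ldS = np.linalg.slogdet(S)
            loglik += -0.5 * (d_obs * _LOG_2PI + ldS + resid @ np.linalg.solve(S, resid))
        means.append(m.copy())
        covs.append(P.copy())
    return KalmanResult(means=means, covs=covs, log_evidence=float(loglik))
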