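"""Linear Gaussian dynamical systems as factor graphs.

The model is

    p(s_0) prod_t p(s_t | s_{t-1}) p(o_t | s_t),
    p(s_t | s_{t-1}) = N(s_t | B s_{t-1}, var_s),
    p(o_t | s_t)     = N(o_t | A s_t, var_o).

Each time slice is built from primitive nodes (gain, noise addition,
equality branch, observation gain/noise); Kalman filtering is the 7-message
sum-product sequence per slice.  With a scalar gain beta carrying a Gaussian
prior, the gain is learned by alternating variational (mean-field)
coordinate updates of the states with the Gaussian gain message, monitoring
the free energy every sweep.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from ..beliefs import VACUOUS, GaussianBelief, Marginal, PointMass, Vacuous
from ..free_energy import (
    FreeEnergyError,
    GaussianBlock,
    ProposalSet,
    free_energy,
    mean_field_step,
)
from ..graph import (
    FactorNode,
    Graph,
    GraphSpecError,
    LogicalFactor,
    RealDomain,
    VariableEdge,
)
from ..rules import gain_variational, gaussian_rule

__all__ = [
    "LGDSSpec",
    "SyntheticTrajectory",
    "build_lgds_chain",
    "kalman_step",
    "kalman_filter",
    "learn_gain",
    "GainLearningResult",
    "simulate_lgds",
    "controlled_lgds_logical_graph",
]


def _mat(x) -> np.ndarray:
    return np.atleast_2d(np.asarray(x, dtype=float))


def _vec(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


@dataclasses.dataclass
class LGDSSpec:
    """Parameters of a linear Gaussian dynamical system.

    ``A`` observation matrix, ``B`` transition matrix (the scalar gain beta
    when learnable), process/observation noise covariances, Gaussian prior
    on the initial state, and the number of steps ``n``.  A Gaussian prior
    (``m_beta``, ``v_beta``) on a scalar transition gain marks the gain as
    learnable.
    """

    A: Union[float, np.ndarray]
    B: Union[float, np.ndarray]
    var_s: Union[float, np.ndarray]
    var_o: Union[float, np.ndarray]
    m0: Union[float, np.ndarray]
    v0: Union[float, np.ndarray]
    n: int
    m_beta: Optional[float] = None
    v_beta: Optional[float] = None

    def __post_init__(self) -> None:
        ds, do = self.state_dim, self.obs_dim
        if _mat(self.B).shape != (ds, ds):
            raise GraphSpecError("transition matrix must be square in the state dim")
        if _mat(self.A).shape != (do, ds):
            raise GraphSpecError("observation matrix shape mismatch")
        for M in (_mat(self.var_s), _mat(self.var_o), _mat(self.v0)):
            if np.any(np.linalg.eigvalsh(M) < -1e-12):
                raise GraphSpecError("covariances must be PSD")

    @property
    def state_dim(self) -> int:
        return _vec(self.m0).shape[0]

    @property
    def obs_dim(self) -> int:
        return _mat(self.A).shape[0]

    @property
    def learnable_gain(self) -> bool:
        return self.m_beta is not None


@dataclasses.dataclass
class SyntheticTrajectory:
    """Ancestrally sampled states and observations with ground truth."""

    states: List
    observations: List
    seed: int
    controls: Optional[List] = None


# ----------------------------------------------------------------------------
# graph construction


def build_lgds_chain(spec: LGDSSpec, observations: Optional[Sequence] = None) -> Graph:
    """One chain of time slices: prior, gain/noise transition, equality
    branch to the observation arm (observation gain + noise + terminal)."""
    ds, do = spec.state_dim, spec.obs_dim
    g = Graph()
    sdom, odom = RealDomain(ds), RealDomain(do)

    def edge(name: str, dom, origin=None) -> str:
        g.add_edge(VariableEdge(name, name, dom, origin=origin))
        return name

    edge("s0", sdom)
    g.add_node(FactorNode("prior_s0", "gaussian_prior",
                          {"mean": _vec(spec.m0), "cov": _mat(spec.v0)}, ["s0"]))
    logical = [LogicalFactor("gaussian_prior", ("s0",),
                             {"mean": _vec(spec.m0), "cov": _mat(spec.v0)})]
    prev_out = "s0"
    for t in range(1, spec.n + 1):
        st, st_obs, st_next = f"s{t}", f"s{t}_obs", f"s{t}_next"
        edge(f"s{t}_pred", sdom)
        edge(f"w{t}", sdom)
        edge(st, sdom)
        edge(st_obs, sdom, origin=st)
        edge(st_next, sdom, origin=st)
        edge(f"z{t}", odom)
        edge(f"v{t}", odom)
        edge(f"o{t}", odom)
        g.add_node(FactorNode(f"gainB_{t}", "gain", {"a": _mat(spec.B)},
                              [prev_out, f"s{t}_pred"]))
        g.add_node(FactorNode(f"noise_s_{t}", "gaussian_prior",
                              {"mean": np.zeros(ds), "cov": _mat(spec.var_s)},
                              [f"w{t}"]))
        g.add_node(FactorNode(f"trans_{t}", "addition", {},
                              [f"s{t}_pred", f"w{t}", st]))
        g.add_node(FactorNode(f"eq_s{t}", "equality", {}, [st, st_obs, st_next]))
        g.add_node(FactorNode(f"gainA_{t}", "gain", {"a": _mat(spec.A)},
                              [st_obs, f"z{t}"]))
        g.add_node(FactorNode(f"noise_o_{t}", "gaussian_prior",
                              {"mean": np.zeros(do), "cov": _mat(spec.var_o)},
                              [f"v{t}"]))
        g.add_node(FactorNode(f"obsadd_{t}", "addition", {},
                              [f"z{t}", f"v{t}", f"o{t}"]))
        if observations is not None and observations[t - 1] is not None:
            g.edges[f"o{t}"].observed_value = _vec(observations[t - 1])
            g.add_node(FactorNode(f"obs_{t}", "observation_terminal", {}, [f"o{t}"]))
        prev_name = f"s{t - 1}"
        logical.append(LogicalFactor(
            "linear_gaussian", (st, prev_name),
            {"child": st, "parent": prev_name, "gain": _mat(spec.B),
             "noise_var": _mat(spec.var_s)}))
        logical.append(LogicalFactor(
            "linear_gaussian", (f"o{t}", st),
            {"child": f"o{t}", "parent": st, "gain": _mat(spec.A),
             "noise_var": _mat(spec.var_o)}))
        prev_out = st_next
    g.logical_factors = logical
    return g


# ----------------------------------------------------------------------------
# Kalman filtering as the 7-message slice sequence


def kalman_step(prior_msg: GaussianBelief, o_t, spec: LGDSSpec
                ) -> Tuple[GaussianBelief, float]:
    """One slice of sum-product Kalman filtering.

    Runs the slice schedule: forward through the transition gain and the
    process-noise addition (prediction), the observation delta backward
    through the observation-noise addition and the likelihood gain, and the
    equality fusion of prediction with likelihood (Bayes rule).  Returns the
    normalized posterior and the log-evidence increment log p(o_t | past).
    """
    params_B = {"a": _mat(spec.B)}
    params_A = {"a": _mat(spec.A)}
    noise_s = GaussianBelief.from_moment(np.zeros(spec.state_dim), _mat(spec.var_s))
    pred_pre = gaussian_rule("gain_forward", {"x": prior_msg}, params_B)
    prediction = gaussian_rule("addition", {"x": pred_pre, "y": noise_s}, {})
    if o_t is None or np.isinf(_mat(spec.var_o)).all():
        likelihood = VACUOUS
    else:
        noise_o = GaussianBelief.from_moment(np.zeros(spec.obs_dim), _mat(spec.var_o))
        obs_delta = PointMass(_vec(o_t))
        z_msg = gaussian_rule("subtraction", {"z": obs_delta, "x": noise_o}, {})
        likelihood = gaussian_rule("gain_backward", {"y": z_msg}, params_A)
    fused = gaussian_rule("equality", {"x": prediction, "y": likelihood}, {})
    if isinstance(fused, Vacuous):
        raise GraphSpecError("non-normalizable fusion")
    increment = 0.0 if isinstance(likelihood, Vacuous) else (
        fused.log_integral - prediction.log_integral
    )
    return fused.normalized(), float(increment)


@dataclasses.dataclass
class FilterResult:
    means: List[np.ndarray]
    covs: List[np.ndarray]
    log_evidence: float


def kalman_filter(spec: LGDSSpec, observations: Sequence) -> FilterResult:
    """Filtered posteriors for every step by repeated slice updates."""
    msg = GaussianBelief.from_moment(_vec(spec.m0), _mat(spec.v0))
    means, covs = [], []
    total = 0.0
    for o in observations:
        msg, inc = kalman_step(msg, o, spec)
        total += inc
        means.append(msg.mean)
        covs.append(msg.cov)
    return FilterResult(means, covs, float(total))


# ----------------------------------------------------------------------------
# gain learning (controlled LGDS)


def controlled_lgds_logical_graph(spec: LGDSSpec, observations: Sequence) -> Graph:
    """Logical-factor view of the controlled chain: p(beta) p(s_0)
    prod_t N(s_t | beta s_{t-1}, var_s) N(o_t | A s_t, var_o).  Used for
    free-energy evaluation and mean-field cross-checks."""
    if not spec.learnable_gain or spec.state_dim != 1:
        raise GraphSpecError("gain learning needs a scalar chain with a beta prior")
    g = Graph()
    dom = RealDomain(1)
    g.add_edge(VariableEdge("beta", "beta", dom))
    g.add_edge(VariableEdge("s0", "s0", dom))
    logical = [
        LogicalFactor("gaussian_prior", ("beta",),
                      {"mean": spec.m_beta, "cov": spec.v_beta}),
        LogicalFactor("gaussian_prior", ("s0",), {"mean": spec.m0, "cov": spec.v0}),
    ]
    A = float(_mat(spec.A)[0, 0])
    vo = float(_mat(spec.var_o)[0, 0])
    vs = float(_mat(spec.var_s)[0, 0])
    for t in range(1, spec.n + 1):
        g.add_edge(VariableEdge(f"s{t}", f"s{t}", dom))
        logical.append(LogicalFactor(
            "linear_gaussian", (f"s{t}", f"s{t-1}", "beta"),
            {"child": f"s{t}", "parent": f"s{t-1}", "gain_var": "beta",
             "noise_var": vs}))
        if observations[t - 1] is not None and math.isfinite(vo):
            # slices without evidence contribute no observation factor
            g.add_edge(VariableEdge(f"o{t}", f"o{t}", dom))
            logical.append(LogicalFactor(
                "linear_gaussian", (f"o{t}", f"s{t}"),
                {"child": f"o{t}", "parent": f"s{t}", "gain": A, "noise_var": vo}))
            g.edges[f"o{t}"].observed_value = float(observations[t - 1])
            g.add_node(FactorNode(f"obs_{t}", "observation_terminal", {}, [f"o{t}"]))
    g.logical_factors = logical
    return g


@dataclasses.dataclass
class GainLearningResult:
    """Posterior over the transition gain with diagnostics."""

    beta_mean: float
    beta_sd: float
    posterior: GaussianBelief
    state_means: np.ndarray
    state_vars: np.ndarray
    free_energy_trace: List[float]
    converged: bool
    n_informative_slices: int

    def summary(self) -> str:
        lines = [
            "Gain learning (variational message passing)",
            "-" * 46,
            f"informative slices   {self.n_informative_slices}",
            f"sweeps run           {len(self.free_energy_trace)}",
            f"converged            {self.converged}",
            f"final free energy    {self.free_energy_trace[-1]:.6f}"
            if self.free_energy_trace else "final free energy    n/a",
            f"posterior gain beta  {self.beta_mean:.4f} (sd {self.beta_sd:.4f})",
        ]
        return "\n".join(lines)


def learn_gain(
    spec: LGDSSpec,
    observations: Sequence,
    sweeps: int = 50,
    tol: float = 1e-10,
) -> GainLearningResult:
    """Learn a scalar transition gain by mean-field variational updates.

    Alternates exact coordinate updates of the per-state Gaussian marginals
    with the Gaussian gain message (fused across slices and with the prior).
    The free energy is evaluated every sweep and is non-increasing.  Slices
    whose observation carries no evidence (missing value or infinite
    observation noise) contribute no gain message: with nothing to explain,
    the posterior over the gain stays at its prior.
    """
    if not spec.learnable_gain or spec.state_dim != 1:
        raise GraphSpecError("gain learning needs a scalar chain with a beta prior")
    n = spec.n
    if len(observations) != n:
        raise GraphSpecError("need one observation slot per step")
    vo = float(_mat(spec.var_o)[0, 0])
    A = float(_mat(spec.A)[0, 0])
    vs = float(_mat(spec.var_s)[0, 0])
    informative = [
        t for t in range(1, n + 1)
        if observations[t - 1] is not None and math.isfinite(vo)
    ]
    prior_beta = GaussianBelief.from_moment(spec.m_beta, spec.v_beta)
    if not informative:
        m = np.array([float(spec.m0)] + [np.nan] * n)
        return GainLearningResult(
            float(spec.m_beta), math.sqrt(float(spec.v_beta)), prior_beta,
            m, np.full(n + 1, np.nan), [], True, 0,
        )

    g_logical = controlled_lgds_logical_graph(spec, observations)

    # initialize states by filtering at the prior-mean gain
    init_spec = dataclasses.replace(spec, B=float(spec.m_beta),
                                    m_beta=None, v_beta=None)
    filt = kalman_filter(init_spec, observations)
    m = np.array([float(spec.m0)] + [float(x[0]) for x in filt.means])
    v = np.array([float(spec.v0)] + [float(c[0, 0]) for c in filt.covs])
    mb, vb = float(spec.m_beta), float(spec.v_beta)

    def fe() -> float:
        blocks = [GaussianBlock("beta", mb, vb)]
        blocks += [GaussianBlock(f"s{t}", float(m[t]), float(v[t]))
                   for t in range(n + 1)]
        return free_energy(g_logical, ProposalSet(blocks)).F

    trace: List[float] = []
    converged = False
    for _ in range(sweeps):
        b2 = mb * mb + vb
        # exact coordinate updates of each state marginal, in time order
        for t in range(n + 1):
            W = 0.0
            h = 0.0
            if t == 0:
                W += 1.0 / float(spec.v0)
                h += float(spec.m0) / float(spec.v0)
            else:
                W += 1.0 / vs
                h += mb * m[t - 1] / vs
            if t < n:
                W += b2 / vs
                h += mb * m[t + 1] / vs
            if t >= 1 and t in informative:
                W += A * A / vo
                h += A * float(observations[t - 1]) / vo
            m[t], v[t] = h / W, 1.0 / W
        # gain update: prior fused with the per-slice variational messages
        fused = prior_beta
        for t in informative:
            q_prev = Marginal(f"s{t-1}", GaussianBelief.from_moment(m[t - 1], v[t - 1]), 0.0)
            q_curr = Marginal(f"s{t}", GaussianBelief.from_moment(m[t], v[t]), 0.0)
            res = gain_variational(q_prev, q_curr, vs)
            if not isinstance(res.message.belief, Vacuous):
                fused = fused.multiply(res.message.belief)
        mb, vb = fused.mean_scalar, fused.cov_scalar
        trace.append(fe())
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    return GainLearningResult(
        beta_mean=mb,
        beta_sd=math.sqrt(vb),
        posterior=GaussianBelief.from_moment(mb, vb),
        state_means=m,
        state_vars=v,
        free_energy_trace=trace,
        converged=converged,
        n_informative_slices=len(informative),
    )


# ----------------------------------------------------------------------------
# synthetic data


def simulate_lgds(spec: LGDSSpec, seed: int) -> SyntheticTrajectory:
    """Ancestral sampling of an LGDS trajectory with ground truth retained."""
    rng = np.random.default_rng(seed)
    A, B = _mat(spec.A), _mat(spec.B)
    Q, R = _mat(spec.var_s), _mat(spec.var_o)
    ds, do = spec.state_dim, spec.obs_dim

    def draw(mean, cov, dim):
        if np.allclose(cov, 0.0):
            return np.asarray(mean, float).copy()
        return rng.multivariate_normal(np.asarray(mean, float).ravel(), cov)

    s = draw(_vec(spec.m0), _mat(spec.v0), ds)
    states, obs = [], []
    for _ in range(spec.n):
        s = draw(B @ s, Q, ds)
        o = draw(A @ s, R, do)
        states.append(s.copy())
        obs.append(o.copy())
    return SyntheticTrajectory(states=states, observations=obs, seed=seed)
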