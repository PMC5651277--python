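"""Node-local update rules: closed Gaussian forms, tensor contraction,
terminal/observation messages, the variational rule and its gain message."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.optimize import minimize_scalar

from forneygraph.beliefs import (
    VACUOUS,
    CategoricalBelief,
    GaussianBelief,
    Marginal,
    PointMass,
    Vacuous,
)
from forneygraph.graph import (
    FactorNode,
    FiniteDomain,
    Graph,
    RealDomain,
    VariableEdge,
)
from forneygraph.rules import (
    RuleError,
    gain_variational,
    gaussian_rule,
    observation_message,
    quadrature_message,
    sum_product,
    terminal_message,
    variational,
)


def _toy_graph(kinds):
    """Graph with one node over freshly created edges; kinds gives
    (node_kind, params, edge domains)."""
    g = Graph()
    kind, params, domains = kinds
    eids = []
    for i, dom in enumerate(domains):
        eid = f"e{i}"
        g.add_edge(VariableEdge(eid, eid, dom))
        eids.append(eid)
    g.add_node(FactorNode("n", kind, params, eids))
    return g, eids


class TestGaussianClosedForms:
    def test_addition_means_and_variances_add(self):
        out = gaussian_rule(
            "addition",
            {"x": GaussianBelief.from_moment(1, 2), "y": GaussianBelief.from_moment(3, 4)},
            {},
        )
        assert out.mean_scalar == pytest.approx(4.0)
        assert out.cov_scalar == pytest.approx(6.0)

    def test_subtraction_rule(self):
        out = gaussian_rule(
            "subtraction",
            {"z": GaussianBelief.from_moment(4, 6), "x": GaussianBelief.from_moment(1, 2)},
            {},
        )
        assert out.mean_scalar == pytest.approx(3.0)
        assert out.cov_scalar == pytest.approx(8.0)

    def test_gain_forward_and_backward(self):
        fwd = gaussian_rule("gain_forward", {"x": GaussianBelief.from_moment(1, 3)}, {"a": 2.0})
        assert fwd.mean_scalar == pytest.approx(2.0)
        assert fwd.cov_scalar == pytest.approx(12.0)
        bwd = gaussian_rule("gain_backward", {"y": GaussianBelief.from_moment(4, 8)}, {"a": 2.0})
        assert bwd.mean_scalar == pytest.approx(2.0)
        assert bwd.cov_scalar == pytest.approx(2.0)

    def test_equality_fusion(self):
        out = gaussian_rule(
            "equality",
            {"x": GaussianBelief.from_moment(0, 1), "y": GaussianBelief.from_moment(2, 1)},
            {},
        )
        assert out.mean_scalar == pytest.approx(1.0)
        assert out.cov_scalar == pytest.approx(0.5)

    def test_gain_backward_zero_gain_point_mass_refused(self):
        with pytest.raises(RuleError):
            gaussian_rule("gain_backward", {"y": PointMass(np.array([1.0]))}, {"a": 0.0})

    @pytest.mark.parametrize("kind", ["addition", "subtraction", "gain_forward", "gain_backward"])
    def test_each_rule_agrees_with_quadrature(self, kind, rng):
        a = float(rng.uniform(0.5, 2.0))
        bx = GaussianBelief.from_moment(rng.normal(), rng.uniform(0.3, 1.5))
        by = GaussianBelief.from_moment(rng.normal(), rng.uniform(0.3, 1.5))
        if kind == "addition":
            ref_mean = bx.mean_scalar + by.mean_scalar
            ref_var = bx.cov_scalar + by.cov_scalar
            out = gaussian_rule(kind, {"x": bx, "y": by}, {})
        elif kind == "subtraction":
            ref_mean = bx.mean_scalar - by.mean_scalar
            ref_var = bx.cov_scalar + by.cov_scalar
            out = gaussian_rule(kind, {"z": bx, "x": by}, {})
        elif kind == "gain_forward":
            ref_mean, ref_var = a * bx.mean_scalar, a * a * bx.cov_scalar

            def density(y):
                return math.exp(bx.logpdf_unnorm(y / a)) / a

            m0, _ = integrate.quad(density, -40, 40)
            m1, _ = integrate.quad(lambda y: y * density(y), -40, 40)
            m2, _ = integrate.quad(lambda y: y * y * density(y), -40, 40)
            assert m1 / m0 == pytest.approx(ref_mean, abs=1e-8)
            assert m2 / m0 - (m1 / m0) ** 2 == pytest.approx(ref_var, abs=1e-8)
            out = gaussian_rule(kind, {"x": bx}, {"a": a})
        else:
            ref_mean, ref_var = bx.mean_scalar / a, bx.cov_scalar / a**2
            out = gaussian_rule(kind, {"y": bx}, {"a": a})
        assert out.mean_scalar == pytest.approx(ref_mean, abs=1e-8)
        assert out.cov_scalar == pytest.approx(ref_var, abs=1e-8)

    def test_matrix_gain_consistent_with_scalar_limit(self):
        b = GaussianBelief.from_moment([1.0], [[3.0]])
        fwd = gaussian_rule("gain_forward", {"x": b}, {"a": [[2.0]]})
        assert fwd.mean_scalar == pytest.approx(2.0)
        assert fwd.cov_scalar == pytest.approx(12.0)
        bwd = gaussian_rule("gain_backward", {"y": b}, {"a": [[2.0]]})
        assert bwd.W[0, 0] == pytest.approx(4.0 / 3.0)


class TestSumProduct:
    def test_equality_node_fuses(self):
        g, eids = _toy_graph(("equality", {}, [RealDomain(1)] * 3))
        res = sum_product(
            g.nodes["n"],
            {
                "e0": GaussianBelief.from_moment(0, 1),
                "e1": GaussianBelief.from_moment(2, 1),
            },
            "e2",
            g,
        )
        assert res.message.belief.mean_scalar == pytest.approx(1.0)
        assert res.message.belief.cov_scalar == pytest.approx(0.5)

    def test_vacuous_inbound_yields_marginalized_factor(self, rng):
        table = rng.uniform(0.1, 1, (2, 3, 2))
        g, eids = _toy_graph(
            ("categorical_table", {"table": table},
             [FiniteDomain(2), FiniteDomain(3), FiniteDomain(2)])
        )
        res = sum_product(g.nodes["n"], {"e0": VACUOUS, "e1": VACUOUS}, "e2", g)
        assert np.allclose(
            np.exp(res.message.belief.log_weights), table.sum(axis=(0, 1)), atol=1e-12
        )

    def test_table_contraction_matches_double_sum(self, rng):
        table = rng.uniform(0.05, 1, (2, 2, 2))
        g, _ = _toy_graph(
            ("categorical_table", {"table": table}, [FiniteDomain(2)] * 3)
        )
        w0 = rng.uniform(0.1, 1, 2)
        w1 = rng.uniform(0.1, 1, 2)
        res = sum_product(
            g.nodes["n"],
            {"e0": CategoricalBelief(w0), "e1": CategoricalBelief(w1)},
            "e2",
            g,
        )
        expected = np.einsum("a,b,abc->c", w0, w1, table)
        assert np.allclose(np.exp(res.message.belief.log_weights), expected, atol=1e-12)

    def test_missing_inbound_reported(self, rng):
        g, _ = _toy_graph(
            ("categorical_table", {"table": rng.uniform(0.1, 1, (2, 2))},
             [FiniteDomain(2)] * 2)
        )
        with pytest.raises(RuleError, match="missing"):
            sum_product(g.nodes["n"], {}, "e1", g)


class TestTerminals:
    def test_gaussian_prior_emits_itself(self):
        g, _ = _toy_graph(
            ("gaussian_prior", {"mean": np.array([0.7]), "cov": np.array([[1.3]])},
             [RealDomain(1)])
        )
        res = terminal_message(g.nodes["n"], g)
        assert res.message.belief.mean_scalar == pytest.approx(0.7)
        assert res.message.belief.cov_scalar == pytest.approx(1.3)

    def test_categorical_prior_identity_and_uniform_unit(self):
        g, _ = _toy_graph(
            ("categorical_table", {"table": np.array([0.2, 0.8])}, [FiniteDomain(2)])
        )
        res = terminal_message(g.nodes["n"], g)
        assert np.allclose(res.message.belief.probs, [0.2, 0.8])
        # a uniform prior combines like a vacuous message, up to scale
        u = CategoricalBelief([0.5, 0.5])
        other = CategoricalBelief([0.3, 0.7])
        assert np.allclose(u.multiply(other).normalized().probs, other.probs)

    def test_observation_messages(self):
        e_obs = VariableEdge("o", "o", FiniteDomain(3), endpoints=["n"], observed_value=2)
        res = observation_message(e_obs)
        assert isinstance(res.message.belief, PointMass)
        assert res.message.belief.value == 2
        e_free = VariableEdge("o2", "o2", FiniteDomain(3), endpoints=["n"])
        assert isinstance(observation_message(e_free).message.belief, Vacuous)

    def test_delta_through_observation_model_gives_likelihood(self):
        # o = s + noise, observed o=2, noise N(0,1): likelihood over s is N(2,1)
        lik = gaussian_rule(
            "subtraction",
            {"z": PointMass(np.array([2.0])), "x": GaussianBelief.from_moment(0, 1)},
            {},
        )
        assert lik.mean_scalar == pytest.approx(2.0)
        assert lik.cov_scalar == pytest.approx(1.0)


class TestVariational:
    def test_equality_variational_equals_sum_product(self):
        g, _ = _toy_graph(("equality", {}, [FiniteDomain(2)] * 3))
        inbound = {
            "e0": CategoricalBelief([0.3, 0.7]),
            "e1": CategoricalBelief([0.6, 0.4]),
        }
        sp = sum_product(g.nodes["n"], inbound, "e2", g)
        vmp = variational(g.nodes["n"], inbound, "e2", g)
        assert np.allclose(
            sp.message.belief.normalized().probs, vmp.message.belief.normalized().probs
        )

    def test_table_variational_matches_direct_formula(self, rng):
        table = rng.uniform(0.05, 1, (3, 2, 2))
        g, _ = _toy_graph(
            ("categorical_table", {"table": table},
             [FiniteDomain(3), FiniteDomain(2), FiniteDomain(2)])
        )
        q0 = rng.uniform(0.1, 1, 3); q0 /= q0.sum()
        q1 = rng.uniform(0.1, 1, 2); q1 /= q1.sum()
        res = variational(
            g.nodes["n"],
            {"e0": CategoricalBelief(q0), "e1": CategoricalBelief(q1)},
            "e2",
            g,
        )
        direct = np.exp(np.einsum("a,b,abc->c", q0, q1, np.log(table)))
        assert np.allclose(
            res.message.belief.normalized().probs, direct / direct.sum(), atol=1e-12
        )


class TestGainVariational:
    def _marg(self, m, v):
        return Marginal("s", GaussianBelief.from_moment(m, max(v, 1e-12)), 0.0)

    def test_deterministic_regression_limit(self):
        res = gain_variational(self._marg(1, 1e-12), self._marg(2, 1e-12), 1.0)
        b = res.message.belief
        assert b.mean_scalar == pytest.approx(2.0, abs=1e-6)
        assert b.cov_scalar == pytest.approx(1.0, abs=1e-6)

    def test_zero_centered_prev_marginal(self):
        res = gain_variational(self._marg(0, 1), self._marg(1.7, 0.4), 2.0)
        b = res.message.belief
        assert b.W[0, 0] == pytest.approx((0 + 1) / 2.0)
        assert b.mean_scalar == pytest.approx(0.0)

    def test_degenerate_prev_returns_vacuous(self):
        q = Marginal("s", PointMass(np.array([0.0])), 0.0)
        res = gain_variational(q, self._marg(1, 1), 1.0)
        assert isinstance(res.message.belief, Vacuous)

    def test_maximizer_matches_numerical_integration(self, rng):
        for _ in range(3):
            m1, v1 = rng.normal(), rng.uniform(0.2, 1.0)
            m2, v2 = rng.normal(), rng.uniform(0.2, 1.0)
            vs = rng.uniform(0.3, 1.5)

            def expected_log(b):
                f = (
                    lambda sp, sc: math.exp(-((sp - m1) ** 2) / (2 * v1))
                    / math.sqrt(2 * math.pi * v1)
                    * math.exp(-((sc - m2) ** 2) / (2 * v2))
                    / math.sqrt(2 * math.pi * v2)
                    * (-((sc - b * sp) ** 2) / (2 * vs))
                )
                val, _ = integrate.dblquad(f, -8, 8, -8, 8)
                return val

            opt = minimize_scalar(lambda b: -expected_log(b), bounds=(-6, 6), method="bounded")
            res = gain_variational(self._marg(m1, v1), self._marg(m2, v2), vs)
            assert res.message.belief.mean_scalar == pytest.approx(opt.x, abs=1e-6)


def test_quadrature_fallback_reproduces_gaussian_prior_product():
    factor = lambda x: math.exp(-((x - 1.0) ** 2) / (2 * 0.5)) / math.sqrt(math.pi)
    out = quadrature_message(factor, {}, "x", ["x"])
    assert out.mean_scalar == pytest.approx(1.0, abs=1e-8)
    assert out.cov_scalar == pytest.approx(0.5, abs=1e-8)
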