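"""Free energy: evaluation, surprise/divergence split, evidence by
closing-the-box, mean-field coordinate descent."""

import math

import numpy as np
import pytest

import forneygraph as fg
from forneygraph import oracle
from forneygraph.free_energy import (
    CategoricalBlock,
    FreeEnergyError,
    GaussianBlock,
    ProposalSet,
    decompose,
    evidence,
    free_energy,
    mean_field_step,
)
from forneygraph.graph import build_graph, normalize_shared_variables
from forneygraph.models import LGDSSpec, build_lgds_chain, simulate_lgds
from forneygraph.random_graphs import random_tree_graph, random_tree_spec


def correlated_pair_graph(rng, observed=True):
    t = rng.uniform(0.1, 1.0, (3, 3)).tolist()
    t2 = rng.uniform(0.1, 1.0, (3, 2)).tolist()
    spec = {
        "variables": [
            {"name": "a", "domain": {"type": "finite", "size": 3}},
            {"name": "b", "domain": {"type": "finite", "size": 3}},
            {"name": "c", "domain": {"type": "finite", "size": 2},
             **({"observed": 1} if observed else {})},
        ],
        "factors": [
            {"name": "fab", "kind": "categorical_table", "params": {"table": t},
             "variables": ["a", "b"]},
            {"name": "fbc", "kind": "categorical_table", "params": {"table": t2},
             "variables": ["b", "c"]},
        ],
    }
    return build_graph(spec), np.array(t), np.array(t2)


def exact_posterior_joint(tab_ab, tab_bc, obs_c):
    joint = tab_ab * tab_bc[None, :, obs_c]
    return joint / joint.sum()


class TestFreeEnergyFunctional:
    def test_exact_posterior_attains_negative_log_evidence(self, rng):
        g, tab, tab2 = correlated_pair_graph(rng)
        ex = oracle.enumerate_exact(g)
        q = ProposalSet([CategoricalBlock(("a", "b"), exact_posterior_joint(tab, tab2, 1))])
        rep = free_energy(g, q)
        assert rep.F == pytest.approx(-ex.log_evidence, abs=1e-9)

    def test_prior_proposal_without_observations_matches_direct_sum(self, rng):
        g, tab, tab2 = correlated_pair_graph(rng, observed=False)
        # q: product of the normalized per-variable prior marginals
        joint = np.einsum("ab,bc->abc", tab, tab2)
        joint = joint / joint.sum()
        qa = joint.sum(axis=(1, 2))
        qb = joint.sum(axis=(0, 2))
        qc = joint.sum(axis=(0, 1))
        q = ProposalSet([
            CategoricalBlock(("a",), qa),
            CategoricalBlock(("b",), qb),
            CategoricalBlock(("c",), qc),
        ])
        rep = free_energy(g, q)
        # direct sum: -H[q] - E_q[log f_ab] - E_q[log f_bc]
        direct = (
            float(np.sum(qa * np.log(qa))) + float(np.sum(qb * np.log(qb)))
            + float(np.sum(qc * np.log(qc)))
            - float(np.einsum("a,b,ab->", qa, qb, np.log(tab)))
            - float(np.einsum("b,c,bc->", qb, qc, np.log(tab2)))
        )
        assert rep.F == pytest.approx(direct, abs=1e-10)

    def test_perturbing_q_away_from_posterior_never_decreases_F(self, rng):
        g, tab, tab2 = correlated_pair_graph(rng)
        post = exact_posterior_joint(tab, tab2, 1)
        base = free_energy(g, ProposalSet([CategoricalBlock(("a", "b"), post)])).F
        for _ in range(10):
            noise = rng.uniform(0.5, 1.5, post.shape)
            q = ProposalSet([CategoricalBlock(("a", "b"), post * noise)])
            assert free_energy(g, q).F >= base - 1e-12

    def test_point_mass_block_flagged(self, rng):
        g, _, _ = correlated_pair_graph(rng)
        q = ProposalSet([
            CategoricalBlock(("a",), np.array([1.0, 0.0, 0.0])),
            CategoricalBlock(("b",), np.ones(3) / 3),
        ])
        # a degenerate (but not one-hot on a zero) block is fine; a Gaussian
        # zero-variance block is the degenerate case that must be signaled
        q2 = ProposalSet([GaussianBlock("a", 0.0, 0.0)])
        with pytest.raises(Exception):
            q2.blocks[0].entropy()


class TestDecompose:
    def test_surprise_plus_divergence_identity(self, rng):
        g, tab, tab2 = correlated_pair_graph(rng)
        ex = oracle.enumerate_exact(g)
        qa = np.ones(3) / 3
        q = ProposalSet([
            CategoricalBlock(("a",), qa), CategoricalBlock(("b",), qa)
        ])
        rep = decompose(free_energy(g, q), ex.log_evidence)
        assert rep.F == pytest.approx(rep.surprise + rep.divergence, abs=1e-9)
        assert rep.divergence >= 0

    def test_exact_posterior_has_zero_divergence(self, rng):
        g, tab, tab2 = correlated_pair_graph(rng)
        ex = oracle.enumerate_exact(g)
        q = ProposalSet([CategoricalBlock(("a", "b"), exact_posterior_joint(tab, tab2, 1))])
        rep = decompose(free_energy(g, q), ex.log_evidence)
        assert rep.divergence == pytest.approx(0.0, abs=1e-9)

    def test_mean_field_on_correlated_model_has_positive_divergence(self, rng):
        g, tab, tab2 = correlated_pair_graph(rng)
        ex = oracle.enumerate_exact(g)
        q = ProposalSet([
            CategoricalBlock(("a",), np.ones(3) / 3),
            CategoricalBlock(("b",), np.ones(3) / 3),
        ])
        for it in range(40):
            q = mean_field_step(g, q, it % 2)
        rep = decompose(free_energy(g, q), ex.log_evidence)
        assert rep.divergence > 1e-6


class TestEvidence:
    def test_single_prior_single_observation_closed_form(self):
        g = build_graph(
            {
                "variables": [{"name": "x", "domain": {"type": "finite", "size": 2},
                               "observed": 0}],
                "factors": [
                    {"name": "p", "kind": "categorical_table",
                     "params": {"table": [0.3, 0.7]}, "variables": ["x"]}
                ],
            }
        )
        assert evidence(g) == pytest.approx(math.log(0.3), abs=1e-12)

    def test_gaussian_prior_with_observation(self):
        spec = LGDSSpec(A=1.0, B=1.0, var_s=1e-12, var_o=1.0, m0=0.5, v0=2.0, n=1)
        g = build_lgds_chain(spec, observations=[1.5])
        # o = s + noise with s ~ N(0.5, 2 + 1e-12): log N(1.5 | 0.5, 3)
        expected = -0.5 * math.log(2 * math.pi * 3.0) - 1.0 / 6.0
        assert evidence(g) == pytest.approx(expected, abs=1e-6)

    def test_discrete_instantiations_match_exhaustive_sum(self, rng):
        for _ in range(10):
            g = random_tree_graph(rng)
            ex = oracle.enumerate_exact(g)
            assert evidence(g) == pytest.approx(ex.log_evidence, abs=1e-10)

    def test_lgds_chain_evidence_matches_prediction_error_decomposition(self, rng):
        spec = LGDSSpec(A=1.2, B=0.9, var_s=0.4, var_o=0.3, m0=0.0, v0=1.0, n=8)
        traj = simulate_lgds(spec, 11)
        g = build_lgds_chain(spec, traj.observations)
        ref = oracle.kalman_reference(spec, traj.observations)
        assert evidence(g) == pytest.approx(ref.log_evidence, abs=1e-9)

    def test_loopy_graph_refused(self, rng):
        t = rng.uniform(0.1, 1, (2, 2)).tolist()
        g = build_graph(
            {
                "variables": [
                    {"name": "a", "domain": {"type": "finite", "size": 2}},
                    {"name": "b", "domain": {"type": "finite", "size": 2}},
                ],
                "factors": [
                    {"name": "f1", "kind": "categorical_table", "params": {"table": t},
                     "variables": ["a", "b"]},
                    {"name": "f2", "kind": "categorical_table", "params": {"table": t},
                     "variables": ["a", "b"]},
                ],
            }
        )
        with pytest.raises(FreeEnergyError):
            evidence(g)


class TestMeanField:
    def test_single_joint_block_on_tree_reaches_posterior_in_one_step(self, rng):
        g, tab, tab2 = correlated_pair_graph(rng)
        q = ProposalSet([CategoricalBlock(("a", "b"), np.ones((3, 3)) / 9)])
        q2 = mean_field_step(g, q, 0)
        assert np.allclose(
            q2.blocks[0].probs, exact_posterior_joint(tab, tab2, 1), atol=1e-12
        )

    def test_two_block_updates_converge_to_self_consistent_fixed_point(self, rng):
        g, tab, tab2 = correlated_pair_graph(rng)
        q = ProposalSet([
            CategoricalBlock(("a",), np.ones(3) / 3),
            CategoricalBlock(("b",), np.ones(3) / 3),
        ])
        F_prev = free_energy(g, q).F
        for it in range(60):
            q = mean_field_step(g, q, it % 2)
            F = free_energy(g, q).F
            assert F <= F_prev + 1e-9
            F_prev = F
        # fixed point: both coordinate updates leave q unchanged
        qa = mean_field_step(g, q, 0).blocks[0].probs
        qb = mean_field_step(g, q, 1).blocks[1].probs
        assert np.abs(qa - q.blocks[0].probs).max() < 1e-10
        assert np.abs(qb - q.blocks[1].probs).max() < 1e-10

    def test_free_energy_bound_on_random_trees(self, rng):
        for _ in range(10):
            g = random_tree_graph(rng)
            hidden = sorted({e.origin for e in g.edges.values()
                             if e.observed_value is None and e.origin == e.name
                             and not e.is_auxiliary})
            # uniform mean-field proposal
            blocks = []
            from forneygraph.free_energy import _finite_size, hidden_variables
            for v in hidden_variables(g):
                k = _finite_size(g, v)
                blocks.append(CategoricalBlock((v,), np.ones(k) / k))
            q = ProposalSet(blocks)
            ex = oracle.enumerate_exact(g)
            assert free_energy(g, q).F >= -ex.log_evidence - 1e-9
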