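"""Graph construction, equality normalization, closing-the-box, validation."""

import json

import numpy as np
import pytest

import forneygraph as fg
from forneygraph import oracle
from forneygraph.graph import (
    GraphSpecError,
    build_graph,
    boxed_graph,
    close_box,
    graph_to_dict,
    normalize_shared_variables,
    to_dot,
    validate,
)
from forneygraph.random_graphs import random_tree_spec
from forneygraph.scheduling import composite_message

from conftest import branching_spec, seven_factor_spec


class TestBuildGraph:
    def test_seven_factor_chain_shape(self, seven_factor_graph):
        g = seven_factor_graph
        assert len(g.nodes) == 7
        assert len(g.edges) == 7
        assert g.half_edges() == ["x6"]
        assert validate(g) == []

    def test_single_factor_is_one_half_edge(self):
        g = build_graph(
            {
                "variables": [{"name": "x", "domain": {"type": "finite", "size": 3}}],
                "factors": [
                    {
                        "name": "f",
                        "kind": "categorical_table",
                        "params": {"table": [0.2, 0.3, 0.5]},
                        "variables": ["x"],
                    }
                ],
            }
        )
        assert len(g.nodes) == 1
        assert g.half_edges() == ["x"]

    def test_errors(self):
        base = {
            "variables": [{"name": "x", "domain": {"type": "finite", "size": 2}}],
            "factors": [
                {"name": "f", "kind": "no_such_kind", "params": {}, "variables": ["x"]}
            ],
        }
        with pytest.raises(GraphSpecError, match="unknown"):
            build_graph(base)
        with pytest.raises(GraphSpecError, match="needs 3"):
            build_graph(
                {
                    "variables": [{"name": "x", "domain": {"type": "real", "dim": 1}}],
                    "factors": [{"name": "f", "kind": "addition", "variables": ["x"]}],
                }
            )
        with pytest.raises(GraphSpecError, match="duplicate"):
            build_graph(
                {
                    "variables": [
                        {"name": "x", "domain": {"type": "finite", "size": 2}},
                        {"name": "x", "domain": {"type": "finite", "size": 2}},
                    ],
                    "factors": [],
                }
            )

    def test_round_trip_through_export(self, rng):
        for _ in range(10):
            spec = random_tree_spec(rng)
            g = build_graph(spec)
            g2 = build_graph(json.loads(json.dumps(graph_to_dict(g))))
            assert sorted(g.nodes) == sorted(g2.nodes)
            assert sorted(g.edges) == sorted(g2.edges)
            for nid in g.nodes:
                assert g.nodes[nid].kind == g2.nodes[nid].kind
                assert g.nodes[nid].interface == g2.nodes[nid].interface
                for k, v in g.nodes[nid].parameters.items():
                    assert np.allclose(v, g2.nodes[nid].parameters[k])
            for eid in g.edges:
                assert g.edges[eid].observed_value == g2.edges[eid].observed_value


class TestNormalization:
    def test_three_way_share_becomes_equality_node(self, rng):
        g = normalize_shared_variables(build_graph(branching_spec(rng)))
        assert len(g.nodes) == 4  # fa, fb, fc plus one equality node
        assert len(g.edges) == 6  # x1, x2, x2', x2'', x3, x4
        assert validate(g) == []
        eq = [n for n in g.nodes.values() if n.kind == "equality"]
        assert len(eq) == 1

    def test_idempotent_on_normalized_graphs(self, rng, seven_factor_graph):
        g = normalize_shared_variables(seven_factor_graph)
        g2 = normalize_shared_variables(g)
        assert sorted(g.nodes) == sorted(g2.nodes)
        assert sorted(g.edges) == sorted(g2.edges)

    def test_marginals_preserved_for_three_way_share(self, rng):
        raw = build_graph(branching_spec(rng))
        norm = normalize_shared_variables(raw)
        ex = oracle.enumerate_exact(raw)
        marg, _, _ = fg.run(norm, fg.tree_schedule(norm), max_sweeps=2)
        for v in ["x1", "x2", "x3", "x4"]:
            assert np.allclose(marg[v].belief.probs, ex.marginals[v], atol=1e-12)

    def test_four_way_share_uses_arity_three_chain(self, rng):
        def t(*s):
            return rng.uniform(0.1, 1, s).tolist()

        spec = {
            "variables": [{"name": "y", "domain": {"type": "finite", "size": 2}}]
            + [
                {"name": f"x{i}", "domain": {"type": "finite", "size": 2}}
                for i in range(4)
            ],
            "factors": [
                {
                    "name": f"f{i}",
                    "kind": "categorical_table",
                    "params": {"table": t(2, 2)},
                    "variables": ["y", f"x{i}"],
                }
                for i in range(4)
            ],
        }
        raw = build_graph(spec)
        norm = normalize_shared_variables(raw)
        eq_nodes = [n for n in norm.nodes.values() if n.kind == "equality"]
        assert len(eq_nodes) == 2
        assert all(len(n.interface) == 3 for n in eq_nodes)
        ex = oracle.enumerate_exact(raw)
        marg, _, _ = fg.run(norm, fg.tree_schedule(norm), max_sweeps=2)
        for v in ["y", "x0", "x1", "x2", "x3"]:
            assert np.allclose(marg[v].belief.probs, ex.marginals[v], atol=1e-12)


class TestCloseBox:
    def test_box_around_left_subchain_has_one_boundary_edge(self, rng):
        spec = seven_factor_spec(rng)
        g = build_graph(spec)
        comp = close_box(g, {"fa", "fb", "fc"})
        assert comp.boundary == ["x3"]
        msg = composite_message(comp, {}, "x3")
        # the outgoing message equals the marginalized boxed product
        fa = np.array(spec["factors"][0]["params"]["table"])
        fb = np.array(spec["factors"][1]["params"]["table"])
        fc = np.array(spec["factors"][2]["params"]["table"])
        expected = np.einsum("a,b,abc->c", fa, fb, fc)
        assert np.allclose(np.exp(msg.log_weights), expected, atol=1e-12)

    def test_singleton_box_behaves_like_the_node(self, rng):
        spec = seven_factor_spec(rng)
        g = build_graph(spec)
        comp = close_box(g, {"fg"})
        msg = composite_message(comp, {}, "x7")
        fgt = np.array(spec["factors"][6]["params"]["table"])
        assert np.allclose(np.exp(msg.log_weights), fgt, atol=1e-12)

    def test_external_marginals_invariant_under_boxing(self, rng):
        for _ in range(5):
            spec = random_tree_spec(rng, max_vars=5, observe_prob=0.0)
            g = build_graph(spec)
            ex = oracle.enumerate_exact(g)
            some = sorted(g.nodes)[: max(1, len(g.nodes) // 2)]
            try:
                g2 = boxed_graph(g, some, "box")
            except GraphSpecError:
                continue  # disconnected or boundary-free selection
            marg, _, _ = fg.run(g2, fg.tree_schedule(g2), max_sweeps=2)
            for eid, m in marg.items():
                assert np.allclose(
                    m.belief.probs, ex.marginals[eid], atol=1e-12
                ), eid

    def test_empty_box_refused(self, seven_factor_graph):
        with pytest.raises(GraphSpecError):
            close_box(seven_factor_graph, set())
        with pytest.raises(GraphSpecError, match="boundary"):
            close_box(seven_factor_graph, set(seven_factor_graph.nodes))


class TestValidate:
    def test_overfull_edge_violation_cites_rule(self, rng):
        g = build_graph(branching_spec(rng))
        msgs = validate(g)
        assert any("at most 2" in m and "x2" in m for m in msgs)

    def test_dangling_reference_names_missing_id(self, seven_factor_graph):
        g = seven_factor_graph
        g.nodes["fa"].interface.append("ghost")
        msgs = validate(g)
        assert any("ghost" in m for m in msgs)


def test_dot_export_is_deterministic(seven_factor_graph):
    d1 = to_dot(seven_factor_graph)
    d2 = to_dot(seven_factor_graph)
    assert d1 == d2
    assert '"fa"' in d1 and "x6" in d1
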