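"""Exact inference: message passing vs. enumeration, decisions, robustness."""

import numpy as np
import pytest

from eatbn.cpt import CPTBank, CPTTable
from eatbn.inference import brute_force_posterior, classify, infer_posterior
from eatbn.simulate import random_tree_model
from eatbn.structure import (
    BINARY_STATES,
    EdgeSpec,
    ModularBNStructure,
    NodeSpec,
    SubmoduleSpec,
)


def chain_model(p_q=0.3, p_a=(0.8, 0.2), p_b=(0.9, 0.4)):
    """Q -> A -> B with hand-set binary CPTs (probabilities of 'true')."""
    nodes = {
        "Q": NodeSpec("Q", "query", BINARY_STATES, "main"),
        "A": NodeSpec("A", "inference", BINARY_STATES, "main"),
        "B": NodeSpec("B", "evidence", BINARY_STATES, "main"),
    }
    edges = [EdgeSpec("Q", "A"), EdgeSpec("A", "B")]
    main = SubmoduleSpec("main", "Q", frozenset(nodes), frozenset(edges))
    structure = ModularBNStructure(nodes=nodes, edges=edges, main_module=main)
    tables = {
        "Q": CPTTable("Q", (), BINARY_STATES, {(): np.array([p_q, 1 - p_q])}),
        "A": CPTTable("A", ("Q",), BINARY_STATES, {
            ("true",): np.array([p_a[0], 1 - p_a[0]]),
            ("false",): np.array([p_a[1], 1 - p_a[1]]),
        }),
        "B": CPTTable("B", ("A",), BINARY_STATES, {
            ("true",): np.array([p_b[0], 1 - p_b[0]]),
            ("false",): np.array([p_b[1], 1 - p_b[1]]),
        }),
    }
    return structure, CPTBank(tables=tables, alpha=0.0)


def random_evidence(structure, rng, p_observe=0.6):
    return {
        nid: ("true" if rng.random() < 0.5 else "false")
        for nid in structure.evidence_nodes
        if rng.random() < p_observe
    }


class TestInferPosterior:
    def test_no_evidence_returns_prior(self):
        structure, cpts = chain_model(p_q=0.3)
        rep = infer_posterior(structure, cpts, {})
        assert rep.query_posterior == pytest.approx(0.3, abs=1e-12)

    def test_hand_computed_chain_posterior(self):
        # P(B=t|Q=t)=0.8*0.9+0.2*0.4=0.80; P(B=t|Q=f)=0.2*0.9+0.8*0.4=0.50
        # posterior = 0.3*0.80 / (0.3*0.80 + 0.7*0.50) = 24/59
        structure, cpts = chain_model()
        rep = infer_posterior(structure, cpts, {"B": "true"})
        assert rep.query_posterior == pytest.approx(24 / 59, abs=1e-12)

    def test_deterministic_cpts_consistent_evidence(self):
        structure, cpts = chain_model(p_q=0.5, p_a=(1.0, 0.0), p_b=(1.0, 0.0))
        rep = infer_posterior(structure, cpts, {"B": "true"})
        assert rep.query_posterior == pytest.approx(1.0)

    def test_invalid_evidence_state(self):
        structure, cpts = chain_model()
        with pytest.raises(ValueError, match="maybe"):
            infer_posterior(structure, cpts, {"B": "maybe"})

    def test_unknown_evidence_node(self):
        structure, cpts = chain_model()
        with pytest.raises(ValueError, match="unknown"):
            infer_posterior(structure, cpts, {"Z": "true"})

    def test_complement_sums_to_one(self, trained_model, synthetic_dataset):
        _, _, windows = synthetic_dataset
        rep = trained_model.posterior(windows[0].features)
        # binary query: posterior of 'false' is the complement by construction
        assert 0.0 <= rep.query_posterior <= 1.0

    def test_oracle_agreement_random_models(self):
        worst = 0.0
        for seed in range(30):
            n = 3 + seed % 12
            structure, cpts = random_tree_model(n, seed)
            rng = np.random.default_rng(500 + seed)
            ev = random_evidence(structure, rng)
            a = infer_posterior(structure, cpts, ev).query_posterior
            b = brute_force_posterior(structure, cpts, ev)
            worst = max(worst, abs(a - b))
        assert worst <= 1e-10

    def test_submodule_order_independence(self, trained_model, synthetic_dataset):
        _, _, windows = synthetic_dataset
        model = trained_model
        ev = model.evidence_for(windows[0].features)
        base = infer_posterior(model.structure, model.cpts, ev).query_posterior
        reordered = model.structure.copy()
        reordered.submodules = list(reversed(reordered.submodules))
        reordered.edges = list(reversed(reordered.edges))
        again = infer_posterior(reordered, model.cpts, ev).query_posterior
        assert again == pytest.approx(base, abs=1e-12)

    def test_shared_node_posteriors_reported(self, trained_model, synthetic_dataset):
        _, _, windows = synthetic_dataset
        rep = trained_model.posterior(windows[0].features)
        assert set(rep.shared_node_posteriors) == {
            "subject_property", "object_property", "spatial_property", "temporal_property",
        }
        for p in rep.shared_node_posteriors.values():
            assert 0.0 <= p <= 1.0

    def test_shared_node_posterior_matches_enumeration(self):
        # the shared-node report must be the exact marginal, not an approximation
        structure, cpts = random_tree_model(7, seed=42)
        sub_root = structure.children_of(structure.query_node)[0]
        structure.submodules = [
            SubmoduleSpec("sub", sub_root, frozenset({sub_root}), frozenset())
        ]
        rng = np.random.default_rng(0)
        ev = random_evidence(structure, rng)
        rep = infer_posterior(structure, cpts, ev)
        oracle = _marginal_via_enumeration(structure, cpts, ev, sub_root)
        assert rep.shared_node_posteriors[sub_root] == pytest.approx(oracle, abs=1e-10)


def _marginal_via_enumeration(structure, cpts, ev, node):
    """P(node = first state | ev) by brute force over the joint."""
    import itertools

    nodes = structure.topological_order()
    parent = {n: structure.parent_of(n) for n in nodes}
    first = structure.nodes[node].states[0]
    num = den = 0.0
    for config in itertools.product(*[structure.nodes[n].states for n in nodes]):
        a = dict(zip(nodes, config))
        if any(a[n] != s for n, s in ev.items()):
            continue
        p = 1.0
        for n in nodes:
            t = cpts.tables[n]
            combo = () if parent[n] is None else (a[parent[n]],)
            p *= float(t.row(combo)[t.states.index(a[n])])
        den += p
        if a[node] == first:
            num += p
    return num / den


class TestBruteForce:
    def test_single_node_prior(self):
        structure, cpts = random_tree_model(1, seed=0)
        prior = cpts.tables["n0"].row(())[0]
        assert brute_force_posterior(structure, cpts, {}) == pytest.approx(float(prior))

    def test_refuses_large_state_space(self):
        structure, cpts = random_tree_model(25, seed=0)
        with pytest.raises(ValueError, match="2\\^20"):
            brute_force_posterior(structure, cpts, {})

    def test_hand_computed_chain(self):
        structure, cpts = chain_model()
        assert brute_force_posterior(structure, cpts, {"B": "true"}) == pytest.approx(
            24 / 59, abs=1e-12
        )


class TestClassify:
    def test_paper_default_threshold(self):
        assert classify(0.61, 0.6) == "eating"

    def test_zero_threshold_always_eating(self):
        for p in (0.0, 0.3, 0.9):
            assert classify(p, 0.0) == "eating"

    def test_tie_is_eating(self):
        assert classify(0.6, 0.6) == "eating"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.5, 0.6)

    def test_monotone_in_threshold(self):
        # lowering the threshold never flips eating -> non-eating
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = float(rng.random())
            thresholds = sorted(rng.random(5), reverse=True)
            decisions = [classify(p, t) == "eating" for t in thresholds]
            assert decisions == sorted(decisions)  # False..True monotone


class TestMissingEvidence:
    def test_posterior_defined_with_partial_evidence(self, trained_model, synthetic_dataset):
        _, _, windows = synthetic_dataset
        model = trained_model
        ev = model.evidence_for(windows[0].features)
        # drop evidence one node at a time; posterior must stay defined
        for node in list(ev)[:10]:
            reduced = {k: v for k, v in ev.items() if k != node}
            rep = infer_posterior(model.structure, model.cpts, reduced)
            assert 0.0 < rep.query_posterior < 1.0

    def test_single_submodule_evidence_stays_interior(self, trained_model, synthetic_dataset):
        _, _, windows = synthetic_dataset
        model = trained_model
        ev = model.evidence_for(windows[0].features)
        spatial = {
            k: v for k, v in ev.items()
            if model.structure.nodes[k].module_id == "spatial"
        }
        assert spatial  # the submodule is observed
        rep = infer_posterior(model.structure, model.cpts, spatial)
        assert 0.0 < rep.query_posterior < 1.0
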