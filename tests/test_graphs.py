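"""PC search, collider orientation, Meek closure and the d-separation oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest

from icfgraphs import (
    Skeleton,
    dag_to_cpdag,
    dsep_oracle,
    oracle_ci_test,
    orient_cpdag,
    pc_skeleton,
    sample_random_dag,
    simulate_dataset,
)
from icfgraphs.graphs import Edge
from conftest import chain_model, random_outcome_model
from oracles import cpdag_by_class_enumeration, dsep_by_path_enumeration


def _oracle_pc(dag):
    skel, seps = pc_skeleton(None, ci_test=oracle_ci_test(dag),
                             nodes=list(dag.nodes),
                             max_cond_size=max(1, len(dag.nodes) - 2))
    return skel, seps


class TestDsepOracle:
    def test_chain_textbook_cases(self):
        dag = nx.DiGraph([("b110", "d120"), ("d120", "s130")])
        assert dsep_oracle(dag, "b110", "s130", {"d120"})
        assert not dsep_oracle(dag, "b110", "s130", set())

    def test_collider_textbook_cases(self, collider_dag):
        assert dsep_oracle(collider_dag, "b110", "s130", set())
        assert not dsep_oracle(collider_dag, "b110", "s130", {"d120"})

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(4, 8))
        dag = sample_random_dag(p, float(rng.uniform(1, 3)), seed + 100)
        nodes = list(dag.nodes)
        for x, y in itertools.combinations(nodes, 2):
            rest = [v for v in nodes if v not in (x, y)]
            for r in range(len(rest) + 1):
                for S in itertools.combinations(rest, r):
                    assert dsep_oracle(dag, x, y, S) == \
                        dsep_by_path_enumeration(dag, x, y, S)


class TestPcSkeleton:
    def test_invalid_alpha_rejected(self):
        model = chain_model()
        data = simulate_dataset(model, 100, 0)
        with pytest.raises(ValueError):
            pc_skeleton(data, alpha=1.5)

    def test_chain_skeleton_recovered_from_data(self):
        hits = 0
        runs = 50
        for s in range(runs):
            data = simulate_dataset(chain_model(), 5000, s)
            skel, _ = pc_skeleton(data, alpha=0.05, seed=s)
            expected = {Edge(("b110", "d120")), Edge(("d120", "s130"))}
            hits += skel.edges == expected
        assert hits >= 0.9 * runs

    def test_false_edge_rate_bounded_on_independent_columns(self):
        total_false = 0
        runs = 100
        for s in range(runs):
            rng = np.random.default_rng(s)
            import pandas as pd
            frame = pd.DataFrame(
                (rng.random((300, 5)) < 0.5).astype(float),
                columns=["b110", "d120", "s130", "e140", "b150"])
            skel, _ = pc_skeleton(frame, alpha=0.01, seed=s)
            total_false += len(skel.edges)
        # 10 pairs at alpha=0.01; Fisher is conservative, allow 2x slack
        assert total_false / runs <= 0.01 * 10 * 2

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_pc_recovers_true_skeleton(self, seed):
        dag = sample_random_dag(int(3 + seed % 6), 2.0, seed)
        skel, _ = _oracle_pc(dag)
        assert skel.edges == {Edge(e) for e in dag.edges}

    def test_edge_count_monotone_in_alpha(self):
        data = simulate_dataset(random_outcome_model(8, 31), 1500, 2)
        counts = []
        for alpha in (0.2, 0.1, 0.05, 0.01, 0.001):
            skel, _ = pc_skeleton(data, alpha=alpha, seed=7)
            counts.append(len(skel.edges))
        assert counts == sorted(counts, reverse=True)


class TestOrientation:
    def test_collider_oriented_from_oracle_sepsets(self, collider_dag):
        skel, seps = _oracle_pc(collider_dag)
        cp = orient_cpdag(skel, seps)
        assert cp.directed == {("b110", "d120"), ("s130", "d120")}
        assert cp.undirected == set()

    def test_chain_stays_undirected(self):
        dag = nx.DiGraph([("b110", "d120"), ("d120", "s130")])
        skel, seps = _oracle_pc(dag)
        cp = orient_cpdag(skel, seps)
        assert cp.directed == set()
        assert cp.undirected == {Edge(("b110", "d120")), Edge(("d120", "s130"))}

    def test_empty_skeleton_gives_empty_cpdag(self):
        skel = Skeleton(["b110", "d120"], set())
        cp = orient_cpdag(skel, {Edge(("b110", "d120")): ()})
        assert cp.directed == set() and cp.undirected == set()

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_pipeline_matches_equivalence_class_enumeration(self, seed):
        """On p <= 5 the CPDAG from oracle PC must equal the one obtained by
        brute-force enumeration of all Markov-equivalent DAGs."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 6))
        dag = sample_random_dag(p, float(rng.uniform(0.8, 2.5)), seed + 500)
        skel, seps = _oracle_pc(dag)
        cp = orient_cpdag(skel, seps)
        directed, undirected, members = cpdag_by_class_enumeration(dag)
        assert cp.directed == directed
        assert cp.undirected == undirected
        assert len(members) >= 1

    @pytest.mark.parametrize("seed", range(10))
    def test_output_v_structures_are_true_colliders(self, seed):
        dag = sample_random_dag(6, 2.0, seed + 900)
        skel, seps = _oracle_pc(dag)
        cp = orient_cpdag(skel, seps)
        und = dag.to_undirected()
        for a, z, b in cp.v_structures():
            assert dag.has_edge(a, z) and dag.has_edge(b, z)
            assert not und.has_edge(a, b)

    def test_dag_to_cpdag_agrees_with_oracle_pc(self):
        for seed in range(20):
            dag = sample_random_dag(7, 2.0, seed + 50)
            skel, seps = _oracle_pc(dag)
            cp = orient_cpdag(skel, seps)
            tc = dag_to_cpdag(dag)
            assert cp.directed == tc.directed
            assert cp.undirected == tc.undirected


def test_cpdag_skeleton_matches_input_skeleton():
    data = simulate_dataset(random_outcome_model(8, 77), 1000, 3)
    skel, seps = pc_skeleton(data, seed=5)
    cp = orient_cpdag(skel, seps)
    assert cp.skeleton().edges == skel.edges
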