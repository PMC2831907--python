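"""IDA-style parent-set enumeration, effect multisets and ranking."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from icfgraphs import (
    Cpdag,
    IcfDataset,
    attach_outcome,
    dag_to_cpdag,
    effect_estimates,
    possible_parent_sets,
    rank_categories,
    sample_coefficients,
    sample_random_dag,
    simulate_dataset,
    true_intervention_effect,
)
from icfgraphs.causal import EffectTable
from icfgraphs.graphs import Edge
from conftest import random_outcome_model
from oracles import parent_sets_by_class_enumeration


class TestPossibleParentSets:
    def test_fully_directed_parents_are_unambiguous(self):
        cp = Cpdag(["b110", "d120", "s130"],
                   directed={("b110", "d120")},
                   undirected=set())
        assert possible_parent_sets(cp, "d120") == [("b110",)]

    def test_single_undirected_edge_gives_both_options(self):
        cp = Cpdag(["b110", "d120"], set(), {Edge(("b110", "d120"))})
        assert possible_parent_sets(cp, "b110") == [(), ("d120",)]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_equivalence_class_extension_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 7))
        dag = sample_random_dag(p, float(rng.uniform(0.8, 3.0)), seed + 77)
        cp = dag_to_cpdag(dag)
        for x in cp.nodes:
            assert possible_parent_sets(cp, x) == \
                parent_sets_by_class_enumeration(cp, x)

    def test_unknown_node_rejected(self):
        cp = Cpdag(["b110"], set(), set())
        with pytest.raises(ValueError):
            possible_parent_sets(cp, "zzz")


class TestEffectEstimates:
    def test_isolated_category_recovers_regression_slope(self):
        rng = np.random.default_rng(0)
        x = (rng.random(10_000) < 0.5).astype(float)
        y = 2.0 * x + rng.normal(0, 1, 10_000)
        data = IcfDataset(pd.DataFrame({"b110": x}),
                          pd.Series(y, name="ghp"))
        cp = Cpdag(["b110"], set(), set())
        ests = effect_estimates(data, cp, "b110")
        se = 1 / (np.sqrt(10_000) * 0.5)
        assert len(ests) == 1
        assert abs(ests[0] - 2.0) < 3 * se

    def test_independent_outcome_gives_null_estimates(self):
        model = sample_coefficients(sample_random_dag(5, 2.0, 3), seed=4)
        model = attach_outcome(model, {}, noise_sd=1.0)
        data = simulate_dataset(model, 20_000, 5)
        cp = dag_to_cpdag(model.dag)
        for x in model.nodes:
            for est in effect_estimates(data, cp, x):
                assert abs(est) < 4 / np.sqrt(20_000) / 0.2

    def test_zero_variance_category_yields_empty_multiset(self):
        data = IcfDataset(pd.DataFrame({"b110": [0.0] * 20}),
                          pd.Series(np.arange(20.0), name="ghp"))
        cp = Cpdag(["b110"], set(), set())
        with pytest.warns(UserWarning):
            assert effect_estimates(data, cp, "b110") == []

    @pytest.mark.parametrize("seed", range(5))
    def test_multiset_contains_true_effect_with_oracle_cpdag(self, seed):
        model = random_outcome_model(int(4 + seed % 3), 200 + seed)
        data = simulate_dataset(model, 50_000, seed)
        cp = dag_to_cpdag(model.dag)
        for x in model.nodes:
            true = true_intervention_effect(model, x, "ghp")
            ests = effect_estimates(data, cp, x)
            assert ests, "every node should yield at least one estimate"
            # crude 3-sigma bound for a binary regressor's OLS slope
            tol = 3 * model.outcome_spec.noise_sd / (np.sqrt(50_000) * 0.15)
            assert min(abs(e - true) for e in ests) < max(tol, 0.1)


class TestEffectTableAndRanking:
    def test_single_estimate_is_its_own_mean(self):
        table = EffectTable({"b110": [1.5], "d120": [-2.0]})
        assert table.means["b110"] == 1.5
        assert table.ranks == {"d120": 1, "b110": 2}

    def test_most_negative_mean_ranks_first(self):
        table = EffectTable({"b110": [-3.0, -1.0], "d120": [0.5], "s130": [-5.0]})
        frame = table.to_frame()
        assert list(frame["code"]) == ["s130", "b110", "d120"]
        assert list(frame["rank"]) == [1, 2, 3]
        assert frame.loc[0, "min"] == -5.0 and frame.loc[0, "max"] == -5.0

    def test_mean_aggregation_invariant_to_dataset_order(self):
        model = random_outcome_model(5, 301)
        d1 = simulate_dataset(model, 800, 1)
        d2 = simulate_dataset(model, 800, 2)
        t12 = rank_categories([d1, d2], seed=9)
        t21 = rank_categories([d2, d1], seed=9)
        for c in t12.estimates:
            assert sorted(t12.estimates[c]) == pytest.approx(
                sorted(t21.estimates[c]))
        assert t12.means == pytest.approx(t21.means)

    def test_dominant_negative_category_ranks_first(self):
        wins = 0
        runs = 5
        for r in range(runs):
            dag = sample_random_dag(8, 1.5, 400 + r)
            model = sample_coefficients(dag, seed=500 + r)
            root = sorted(v for v in model.nodes if dag.in_degree(v) == 0)[0]
            model = attach_outcome(model, {root: -6.0}, noise_sd=8.0)
            data = simulate_dataset(model, 3000, 600 + r)
            table = rank_categories([data], seed=700 + r)
            wins += table.top(1)[0] == root
        assert wins >= 4
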