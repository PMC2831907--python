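"""Generator correctness: DAG sampling, coefficient validity, simulation
fidelity, exact do-effects and MCAR missingness."""

import itertools

import networkx as nx
import numpy as np
import pytest

from icfgraphs import (
    TrueModel,
    attach_outcome,
    inject_missingness,
    sample_coefficients,
    sample_random_dag,
    simulate_dataset,
    true_intervention_effect,
)
from conftest import chain_model, random_outcome_model
from oracles import path_product_effect


class TestSampleRandomDag:
    def test_single_node_has_no_edges(self):
        dag = sample_random_dag(1, 3.0, 0)
        assert dag.number_of_nodes() == 1 and dag.number_of_edges() == 0

    def test_zero_degree_gives_empty_graph(self):
        assert sample_random_dag(10, 0.0, 1).number_of_edges() == 0

    def test_rejects_non_positive_p(self):
        with pytest.raises(ValueError):
            sample_random_dag(0, 1.0, 0)

    def test_always_acyclic(self):
        for s in range(20):
            assert nx.is_directed_acyclic_graph(sample_random_dag(8, 3.0, s))

    def test_mean_edge_count_matches_binomial(self):
        # p=6, degree 2: edges ~ Binomial(15, 2/5), mean 6
        counts = [sample_random_dag(6, 2.0, s).number_of_edges()
                  for s in range(500)]
        se = np.sqrt(15 * 0.4 * 0.6 / 500)
        assert abs(np.mean(counts) - 6.0) < 3 * se


class TestSampleCoefficients:
    def test_edgeless_dag_gets_interior_intercepts(self):
        dag = sample_random_dag(5, 0.0, 3)
        model = sample_coefficients(dag, seed=4)
        assert all(0.0 < model.intercepts[v] < 1.0 for v in model.nodes)
        assert all(model.weights[v] == {} for v in model.nodes)

    def test_fixed_weight_single_edge_forces_intercept_interval(self):
        dag = nx.DiGraph([("b110", "d120")])
        model = sample_coefficients(dag, weight_range=(0.3, 0.3), seed=0)
        assert model.weights["d120"] == {"b110": pytest.approx(0.3)}
        assert 0.0 <= model.intercepts["d120"] <= 0.7

    @pytest.mark.parametrize("seed", range(10))
    def test_probability_valid_for_all_parent_configurations(self, seed):
        dag = sample_random_dag(10, 3.0, seed)
        model = sample_coefficients(dag, weight_range=(-0.8, 0.8), seed=seed)
        for v in model.nodes:
            pa = sorted(model.weights[v])
            for bits in itertools.product((0, 1), repeat=len(pa)):
                prob = model.intercepts[v] + sum(
                    model.weights[v][q] * b for q, b in zip(pa, bits))
                assert -1e-12 <= prob <= 1 + 1e-12


class TestSimulateDataset:
    def test_zero_intercept_single_node_is_all_zero(self):
        dag = nx.DiGraph()
        dag.add_node("b110")
        model = TrueModel(dag, {"b110": 0.0}, {"b110": {}})
        data = simulate_dataset(model, 50, 0)
        assert (data.values["b110"] == 0.0).all()

    def test_chain_conditional_probability_recovered(self):
        model = chain_model(weight=0.5, intercept=0.25)
        data = simulate_dataset(model, 20_000, 1)
        x, z = data.values["b110"], data.values["d120"]
        diff = z[x == 1].mean() - z[x == 0].mean()
        se = np.sqrt(0.25 / (x == 1).sum() + 0.25 / (x == 0).sum())
        assert abs(diff - 0.5) < 3 * se

    def test_zero_weight_outcome_uncorrelated_with_nodes(self):
        dag = sample_random_dag(5, 2.0, 7)
        model = sample_coefficients(dag, seed=8)
        model = attach_outcome(model, {c: 0.0 for c in model.nodes},
                               noise_sd=1.0)
        data = simulate_dataset(model, 20_000, 9)
        for c in data.codes:
            r = np.corrcoef(data.values[c], data.outcome)[0, 1]
            assert abs(r) < 3 / np.sqrt(20_000)

    def test_identical_seeds_reproduce_bit_for_bit(self):
        model = random_outcome_model(6, 11)
        a = simulate_dataset(model, 500, 42)
        b = simulate_dataset(model, 500, 42)
        assert a.values.equals(b.values) and a.outcome.equals(b.outcome)

    def test_cells_are_strictly_binary(self):
        model = random_outcome_model(8, 13)
        data = simulate_dataset(model, 1000, 5)
        assert set(np.unique(data.values.to_numpy())) <= {0.0, 1.0}


class TestTrueInterventionEffect:
    def test_no_directed_path_gives_zero(self):
        dag = nx.DiGraph()
        dag.add_nodes_from(["b110", "d120"])
        model = TrueModel(dag, {"b110": 0.4, "d120": 0.6},
                          {"b110": {}, "d120": {}})
        assert true_intervention_effect(model, "b110", "d120") == 0.0

    def test_chain_effect_is_product_of_weights(self):
        model = chain_model(weight=0.5, intercept=0.25)
        eff = true_intervention_effect(model, "b110", "s130")
        assert eff == pytest.approx(0.25)

    def test_direct_outcome_parent_recovers_weight(self):
        dag = nx.DiGraph()
        dag.add_node("b110")
        model = TrueModel(dag, {"b110": 0.5}, {"b110": {}})
        model = attach_outcome(model, {"b110": 0.4}, noise_sd=1.0)
        assert true_intervention_effect(model, "b110", "ghp") == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", range(15))
    def test_enumeration_matches_path_product_closed_form(self, seed):
        model = random_outcome_model(int(3 + seed % 8), 100 + seed)
        for x in model.nodes:
            enum = true_intervention_effect(model, x, "ghp")
            closed = path_product_effect(model, x, "ghp")
            assert enum == pytest.approx(closed, abs=1e-9)


class TestInjectMissingness:
    def test_zero_rate_is_identity(self):
        data = simulate_dataset(random_outcome_model(5, 17), 200, 1)
        out = inject_missingness(data, 0.0, 2)
        assert out.values.equals(data.values)

    def test_rate_one_blanks_the_column(self):
        data = simulate_dataset(random_outcome_model(5, 17), 200, 1)
        out = inject_missingness(data, {data.codes[0]: 1.0}, 2)
        assert out.values[data.codes[0]].isna().all()
        assert out.values[data.codes[1]].notna().all()

    def test_binomial_missing_count(self):
        data = simulate_dataset(random_outcome_model(4, 19), 1000, 3)
        out = inject_missingness(data, 0.2, 4)
        se = np.sqrt(1000 * 0.2 * 0.8)
        for c in out.codes:
            assert abs(out.values[c].isna().sum() - 200) < 3 * se

    def test_outcome_left_untouched_and_rate_validated(self):
        data = simulate_dataset(random_outcome_model(4, 19), 100, 3)
        out = inject_missingness(data, 0.5, 5)
        assert out.outcome.equals(data.outcome)
        with pytest.raises(ValueError):
            inject_missingness(data, 1.5, 0)


def test_model_json_round_trip():
    model = random_outcome_model(7, 23)
    back = TrueModel.from_json(model.to_json())
    assert set(back.dag.edges) == set(model.dag.edges)
    assert back.intercepts == model.intercepts
    assert back.weights == model.weights
    assert back.outcome_spec.weights == model.outcome_spec.weights
    a = simulate_dataset(model, 100, 9)
    b = simulate_dataset(back, 100, 9)
    assert a.values.equals(b.values)
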