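"""Compare the dependence structures of two simulated subpopulations.

Population A and population B are generated from causal models that differ
in 4 of ~10 edges.  Each population is imputed (m=2) and bootstrapped (B=2),
one skeleton is estimated per resampled dataset, and the ensembles are
compared through structural Hamming distances (SHD): the populations are
judged different when the median between-ensemble SHD exceeds the 95th
percentile of the pooled within-ensemble SHDs.
"""

import networkx as nx

from icfgraphs import (
    bootstrap_collection,
    compare_subpopulations,
    impute,
    inject_missingness,
    sample_coefficients,
    sample_random_dag,
    simulate_dataset,
)

dag_a = sample_random_dag(p=10, expected_degree=2.0, seed=21)
dag_b = dag_a.copy()
drop = sorted(dag_b.edges)[:2]
dag_b.remove_edges_from(drop)
order = list(nx.topological_sort(dag_b))
dag_b.add_edge(order[0], order[-1])
dag_b.add_edge(order[1], order[-2])

model_a = sample_coefficients(dag_a, weight_range=(-0.5, 0.5), seed=22)
model_b = sample_coefficients(dag_b, weight_range=(-0.5, 0.5), seed=22)


def collection(model, seed):
    data = simulate_dataset(model, n=2000, seed=seed)
    data = inject_missingness(data, 0.1, seed + 1)
    ens = impute(data, m=2, iterations=3, seed=seed + 2)
    return bootstrap_collection(ens, B=2, seed=seed + 3)


report = compare_subpopulations(collection(model_a, 100),
                                collection(model_b, 200), seed=23)

print(f"decision: {report.decision}")
print(f"median between-SHD: {report.median_between:.1f}")
print(f"95th pct of pooled within-SHD: {report.within_quantile:.1f}")
print("characteristic edges (reliable in one population, absent in the other):")
for edge, ra, rb in report.characteristic_edges:
    print(f"  {edge[0]} -- {edge[1]}: reliability A={ra:.2f}, B={rb:.2f}")
print("\nA larger between- than within-variation means the structural")
print("difference exceeds what bootstrap + imputation noise alone produces.")
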