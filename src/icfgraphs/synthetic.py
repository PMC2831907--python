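"""Ground-truth causal models and simulated ICF-like binary datasets.

The generator emulates the structure the downstream analysis assumes: a sparse
random DAG over ICF-style category codes, main-effects *linear-probability*
structural equations (``P(X_j = 1 | parents) = intercept_j + sum_k w_jk x_k``),
a continuous outcome that is a main-effects linear function of a subset of
categories plus Gaussian noise, and MCAR missingness injected per column.

The linear-probability form (rather than logistic) is deliberate: the
intervention-effect estimator downstream fits interaction-free linear
regressions, and under this data mechanism that estimator is exactly
consistent, which makes parameter-recovery checks sharp instead of
approximate.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import OUTCOME_COLUMN, IcfDataset

#: margin keeping structural probabilities away from exactly 0/1
_PROB_MARGIN = 0.9

_COMPONENT_LETTERS = "bdse"


def make_codes(p: int) -> list[str]:
    """Deterministic ICF-style codes: b110, d120, s130, e140, b150, ..."""
    return [f"{_COMPONENT_LETTERS[i % 4]}{110 + 10 * i}" for i in range(p)]


@dataclass
class OutcomeSpec:
    """Outcome equation: intercept + sum(weights * category) + N(0, noise_sd)."""

    intercept: float
    weights: dict[str, float]
    noise_sd: float


@dataclass
class TrueModel:
    """Synthetic ground truth: DAG + linear-probability coefficients + outcome.

    Invariants: the DAG is acyclic, and for every node
    ``intercept + sum(positive weights) <= 1`` and
    ``intercept + sum(negative weights) >= 0``, so the structural probability
    is valid for every parent configuration.
    """

    dag: nx.DiGraph
    intercepts: dict[str, float]
    weights: dict[str, dict[str, float]]  # node -> {parent: weight}
    outcome_spec: OutcomeSpec | None = None
    seed: int = 0
    rescale_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("model graph must be acyclic")

    @property
    def nodes(self) -> list[str]:
        return list(self.dag.nodes)

    def parents(self, node: str) -> list[str]:
        return sorted(self.dag.predecessors(node))

    def validate_probabilities(self) -> None:
        """Assert the probability-validity invariant for every node."""
        for node in self.dag.nodes:
            w = self.weights.get(node, {})
            a = self.intercepts[node]
            hi = a + sum(v for v in w.values() if v > 0)
            lo = a + sum(v for v in w.values() if v < 0)
            if not (lo >= -1e-12 and hi <= 1 + 1e-12):
                raise ValueError(
                    f"node {node}: probability range [{lo:.4f}, {hi:.4f}] "
                    "escapes [0, 1]"
                )

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "nodes": list(self.dag.nodes),
            "edges": sorted(self.dag.edges),
            "intercepts": self.intercepts,
            "weights": self.weights,
            "seed": self.seed,
            "rescale_factors": self.rescale_factors,
        }
        if self.outcome_spec is not None:
            doc["outcome"] = {
                "intercept": self.outcome_spec.intercept,
                "weights": self.outcome_spec.weights,
                "noise_sd": self.outcome_spec.noise_sd,
            }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrueModel":
        doc = json.loads(text)
        dag = nx.DiGraph()
        dag.add_nodes_from(doc["nodes"])
        dag.add_edges_from(tuple(e) for e in doc["edges"])
        spec = None
        if "outcome" in doc:
            o = doc["outcome"]
            spec = OutcomeSpec(o["intercept"], dict(o["weights"]), o["noise_sd"])
        return cls(
            dag,
            {k: float(v) for k, v in doc["intercepts"].items()},
            {k: {p: float(w) for p, w in d.items()} for k, d in doc["weights"].items()},
            spec,
            int(doc["seed"]),
            {k: float(v) for k, v in doc.get("rescale_factors", {}).items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TrueModel":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_random_dag(p: int, expected_degree: float, seed: int) -> nx.DiGraph:
    """Erdos-Renyi DAG over ``p`` ICF-style codes.

    A random topological order is drawn and each of the p(p-1)/2 ordered pairs
    receives an edge independently with probability
    ``min(1, expected_degree / (p - 1))``, so the expected total degree of a
    node is ``expected_degree``.
    """
    if p < 1:
        raise ValueError("p must be a positive integer")
    if expected_degree < 0:
        raise ValueError("expected_degree must be non-negative")
    rng = np.random.default_rng(seed)
    codes = make_codes(p)
    order = [codes[i] for i in rng.permutation(p)]
    prob = min(1.0, expected_degree / (p - 1)) if p > 1 else 0.0
    dag = nx.DiGraph()
    dag.add_nodes_from(codes)
    for i, j in itertools.combinations(range(p), 2):
        if rng.random() < prob:
            dag.add_edge(order[i], order[j])
    return dag


def sample_coefficients(
    dag: nx.DiGraph,
    weight_range: tuple[float, float] = (-0.5, 0.5),
    seed: int = 0,
) -> TrueModel:
    """Draw linear-probability coefficients that are valid for all inputs.

    Parent weights are drawn uniformly from ``weight_range``.  If the spread
    between the best and worst parent configuration exceeds the probability
    margin, all of the node's weights are shrunk by a common factor (recorded
    in ``rescale_factors``); the intercept is then drawn uniformly from the
    remaining feasible interval.  Rescaling is deterministic and always
    succeeds, unlike rejection sampling.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("dag must be acyclic")
    rng = np.random.default_rng(seed)
    intercepts: dict[str, float] = {}
    weights: dict[str, dict[str, float]] = {}
    rescales: dict[str, float] = {}
    for node in sorted(dag.nodes):
        pa = sorted(dag.predecessors(node))
        w = {q: float(rng.uniform(*weight_range)) for q in pa}
        pos = sum(v for v in w.values() if v > 0)
        neg = sum(v for v in w.values() if v < 0)
        span = pos - neg
        if span > _PROB_MARGIN:
            factor = _PROB_MARGIN / span
            w = {q: v * factor for q, v in w.items()}
            pos, neg = pos * factor, neg * factor
            rescales[node] = factor
        lo, hi = -neg, 1.0 - pos  # feasible intercepts; hi - lo >= 1 - margin
        intercepts[node] = float(rng.uniform(lo, hi))
        weights[node] = w
    model = TrueModel(dag, intercepts, weights, None, seed, rescales)
    model.validate_probabilities()
    return model


def attach_outcome(
    model: TrueModel,
    weights: dict[str, float],
    intercept: float = 60.0,
    noise_sd: float = 10.0,
) -> TrueModel:
    """Return a copy of ``model`` with a continuous-outcome equation.

    Defaults put the outcome on the ghp scale (0-100 health perception score):
    baseline 60 with noise sd 10 is a realistic spread for a patient cohort.
    """
    unknown = set(weights) - set(model.dag.nodes)
    if unknown:
        raise ValueError(f"outcome weights reference unknown nodes: {sorted(unknown)}")
    spec = OutcomeSpec(float(intercept), {k: float(v) for k, v in weights.items()},
                       float(noise_sd))
    return TrueModel(model.dag, model.intercepts, model.weights, spec,
                     model.seed, model.rescale_factors)


def simulate_dataset(model: TrueModel, n: int, seed: int) -> IcfDataset:
    """Sample ``n`` patients from the structural equations.

    Nodes are sampled in topological order; each binary node is Bernoulli with
    its linear-probability mean, which is asserted (not clamped) to lie in
    [0, 1].  The outcome, if specified, is the linear outcome equation plus
    Gaussian noise.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(model.dag):
        prob = np.full(n, model.intercepts[node])
        for parent, w in model.weights.get(node, {}).items():
            prob = prob + w * cols[parent]
        assert (prob >= -1e-12).all() and (prob <= 1 + 1e-12).all(), (
            f"invalid structural probability at node {node}"
        )
        cols[node] = (rng.random(n) < prob).astype(float)
    frame = pd.DataFrame({c: cols[c] for c in model.dag.nodes})
    outcome = None
    if model.outcome_spec is not None:
        spec = model.outcome_spec
        y = np.full(n, spec.intercept, dtype=float)
        for code, w in spec.weights.items():
            y += w * cols[code]
        y += rng.normal(0.0, spec.noise_sd, size=n)
        outcome = pd.Series(y, name=OUTCOME_COLUMN)
    return IcfDataset(frame, outcome, provenance=f"synthetic(seed={seed})")


# ---------------------------------------------------------------------------
# ground-truth intervention effects
# ---------------------------------------------------------------------------

def true_intervention_effect(model: TrueModel, x: str, y: str) -> float:
    """Exact ``E[Y | do(X=1)] - E[Y | do(X=0)]`` by truncated factorization.

    Enumerates every configuration of the non-intervened binary nodes,
    multiplying the structural probabilities with ``X`` held fixed.  ``y`` may
    be a category code or ``"ghp"`` for the continuous outcome, in which case
    the outcome equation is averaged over the interventional distribution.
    Feasible for p <= 16 nodes.
    """
    nodes = list(model.dag.nodes)
    if x not in nodes:
        raise ValueError(f"unknown intervention node {x!r}")
    if len(nodes) > 16:
        raise ValueError("exact enumeration supported only for p <= 16")
    if y == OUTCOME_COLUMN:
        if model.outcome_spec is None:
            raise ValueError("model has no outcome equation")
        target_weights = model.outcome_spec.weights
    elif y in nodes:
        target_weights = {y: 1.0}
    else:
        raise ValueError(f"unknown target {y!r}")

    means = {
        setting: _interventional_means(model, x, setting) for setting in (1.0, 0.0)
    }
    return float(sum(
        w * (means[1.0][code] - means[0.0][code])
        for code, w in target_weights.items()
    ))


def _interventional_means(model: TrueModel, x: str, x_value: float) -> dict[str, float]:
    """E[node | do(x = x_value)] for every node, by exhaustive enumeration."""
    order = [v for v in nx.topological_sort(model.dag)]
    free = [v for v in order if v != x]
    total = {v: 0.0 for v in order}
    for bits in itertools.product((0.0, 1.0), repeat=len(free)):
        config = dict(zip(free, bits))
        config[x] = x_value
        prob = 1.0
        for v in free:  # truncated factorization: drop the factor for x
            mean = model.intercepts[v] + sum(
                w * config[q] for q, w in model.weights.get(v, {}).items()
            )
            prob *= mean if config[v] == 1.0 else (1.0 - mean)
            if prob == 0.0:
                break
        if prob == 0.0:
            continue
        for v in order:
            total[v] += prob * config[v]
    return total


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def inject_missingness(
    data: IcfDataset,
    column_rates: float | dict[str, float],
    seed: int,
) -> IcfDataset:
    """Blank cells completely at random, column by column.

    ``column_rates`` is either one rate for every column or a mapping
    code -> rate; unlisted columns keep rate 0.  The outcome column is never
    touched (outcome missingness is out of scope).
    """
    if isinstance(column_rates, dict):
        rates = {c: float(column_rates.get(c, 0.0)) for c in data.codes}
    else:
        rates = {c: float(column_rates) for c in data.codes}
    bad = {c: r for c, r in rates.items() if not 0.0 <= r <= 1.0}
    if bad:
        raise ValueError(f"missingness rates must lie in [0, 1]: {bad}")
    rng = np.random.default_rng(seed)
    values = data.values.copy()
    for code in data.codes:
        mask = rng.random(len(values)) < rates[code]
        values.loc[mask, code] = np.nan
    outcome = None if data.outcome is None else data.outcome.copy()
    return IcfDataset(values, outcome, provenance=data.provenance)
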