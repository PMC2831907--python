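import logging
import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from icfgraphs import IcfDataset, TrueModel, attach_outcome, sample_coefficients

# keep Monte-Carlo runs quiet: orientation-conflict warnings are expected
logging.getLogger("icfgraphs").setLevel(logging.ERROR)


def chain_model(weight: float = 0.5, intercept: float = 0.25) -> TrueModel:
    """X -> Z -> Y chain with equal edge weights, valid by construction."""
    dag = nx.DiGraph([("b110", "d120"), ("d120", "s130")])
    return TrueModel(
        dag,
        intercepts={"b110": 0.5, "d120": intercept, "s130": intercept},
        weights={"b110": {}, "d120": {"b110": weight}, "s130": {"d120": weight}},
    )


@pytest.fixture
def chain():
    return chain_model()


@pytest.fixture
def collider_dag():
    return nx.DiGraph([("b110", "d120"), ("s130", "d120")])


def binary_frame(arrays: dict[str, list]) -> IcfDataset:
    return IcfDataset(pd.DataFrame({k: np.asarray(v, float) for k, v in arrays.items()}))


def random_outcome_model(p: int, seed: int, expected_degree: float = 2.0,
                         noise_sd: float = 5.0) -> TrueModel:
    """Random linear-probability model with outcome weights on every node."""
    from icfgraphs import sample_random_dag

    rng = np.random.default_rng(seed)
    dag = sample_random_dag(p, expected_degree, seed)
    model = sample_coefficients(dag, seed=seed + 1)
    weights = {c: float(rng.uniform(-8, 8)) for c in model.nodes}
    return attach_outcome(model, weights, noise_sd=noise_sd)
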