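"""Bootstrap aggregation input: B bootstrap replicates per imputed dataset.

Graphical-model estimates are unstable under small data perturbations; the
pipeline therefore estimates one graph per bootstrap replicate of every
imputed dataset and aggregates afterwards.  With m imputations and B
replicates the collection holds m x B datasets (the study design used
m=10, B=10 -> 100 and m=5, B=10 -> 50).  Rows are resampled with replacement
as whole records — the outcome travels with its row — and each (i, b) cell
gets an independently derivable sub-seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import IcfDataset
from .imputation import ImputedEnsemble
from .seeds import child_seed

DEFAULT_B = 10


@dataclass
class ResampledCollection:
    """m x B bootstrap replicates, tagged with (imputation, bootstrap) indices."""

    datasets: list[IcfDataset]
    tags: list[tuple[int, int]]  # 1-based (i, b)
    n: int
    seed: int

    def __post_init__(self) -> None:
        assert len(self.datasets) == len(self.tags)

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)


def bootstrap_dataset(data: IcfDataset, seed: int) -> IcfDataset:
    """One bootstrap replicate: n rows drawn uniformly with replacement."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, data.n, size=data.n)
    values = data.values.iloc[idx].reset_index(drop=True)
    outcome = None
    if data.outcome is not None:
        outcome = data.outcome.iloc[idx].reset_index(drop=True)
    return IcfDataset(values, outcome, provenance=data.provenance)


def bootstrap_collection(
    ensemble: ImputedEnsemble, B: int = DEFAULT_B, seed: int = 0
) -> ResampledCollection:
    """B bootstrap replicates of each of the ensemble's m completed datasets."""
    if B < 1:
        raise ValueError("B must be at least 1")
    datasets: list[IcfDataset] = []
    tags: list[tuple[int, int]] = []
    for i, data in enumerate(ensemble.completed, start=1):
        for b in range(1, B + 1):
            datasets.append(bootstrap_dataset(data, child_seed(seed, "boot", i, b)))
            tags.append((i, b))
    n = ensemble.completed[0].n if ensemble.completed else 0
    return ResampledCollection(datasets, tags, n, seed)
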