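"""Multiple imputation of missing binary cells by chained equations.

Produces ``m`` completed copies of a dataset.  Missing cells are first filled
by sampling observed values of the same column; the sampler then cycles
left-to-right through the incomplete columns for a fixed number of
iterations, each time refitting a main-effects model of the column on all
other columns over the rows where the column was observed, and redrawing the
missing cells:

* ``logistic`` — ridge-penalised logistic regression; imputations are drawn
  from the predicted Bernoulli probabilities.  The small ridge penalty keeps
  the fit finite under complete separation, which is near-certain in wide
  sparse binary tables.
* ``pmm`` — predictive mean matching on a least-squares fit: each missing
  cell copies the observed value of one of the ``k`` donors whose predicted
  values are nearest to the cell's own prediction.

Observed cells are never modified, so all ``m`` completions agree bit-exactly
with the input wherever it was observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .dataset import IcfDataset
from .seeds import child_seed

DEFAULT_M = 10
_DEFAULT_ITERATIONS = 10
DEFAULT_PMM_DONORS = 5
#: inverse ridge strength for the logistic imputation model
_LOGISTIC_C = 10.0

METHODS = ("logistic", "pmm")


class UnimputableColumnError(ValueError):
    """A column has no observed values at all; filter it out first."""


@dataclass
class ImputedEnsemble:
    """m completed datasets plus the settings that produced them."""

    completed: list[IcfDataset]
    m: int
    method: str
    seed: int
    iterations: int

    def __post_init__(self) -> None:
        assert len(self.completed) == self.m


def default_iterations(config=None) -> int:
    """Chained-equations cycle count: 10, unless a config overrides it."""
    if config is not None and getattr(config, "iterations", None) is not None:
        return int(config.iterations)
    return _DEFAULT_ITERATIONS


def impute(
    data: IcfDataset,
    m: int = DEFAULT_M,
    method: str = "logistic",
    iterations: int | None = None,
    seed: int = 0,
    pmm_donors: int = DEFAULT_PMM_DONORS,
) -> ImputedEnsemble:
    """Impute ``data`` ``m`` times with independent sub-seeds."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if iterations is None:
        iterations = default_iterations()
    if iterations < 0:
        raise ValueError("iterations must be non-negative")

    values = data.values.to_numpy(copy=True)
    miss = np.isnan(values)
    dead = [c for c, whole in zip(data.codes, miss.all(axis=0)) if whole]
    if dead:
        raise UnimputableColumnError(
            f"columns entirely missing, cannot impute: {dead}"
        )

    completed = []
    for i in range(m):
        rng = np.random.default_rng(child_seed(seed, "impute", i))
        filled = _impute_once(values, miss, method, iterations, pmm_donors, rng)
        frame = data.values.copy()
        frame.loc[:, :] = filled
        out = None if data.outcome is None else data.outcome.copy()
        completed.append(IcfDataset(frame, out, data.provenance))
    return ImputedEnsemble(completed, m, method, seed, int(iterations))


def _impute_once(values, miss, method, iterations, pmm_donors, rng):
    filled = values.copy()
    incomplete = [j for j in range(values.shape[1]) if miss[:, j].any()]

    # initial fill: sample observed values of the same column
    for j in incomplete:
        obs = values[~miss[:, j], j]
        filled[miss[:, j], j] = rng.choice(obs, size=int(miss[:, j].sum()))

    for _ in range(iterations):
        for j in incomplete:
            rows_mis = miss[:, j]
            rows_obs = ~rows_mis
            y_obs = filled[rows_obs, j]
            others = [k for k in range(values.shape[1]) if k != j]
            X_obs = filled[np.ix_(rows_obs, others)]
            X_mis = filled[np.ix_(rows_mis, others)]
            if method == "logistic":
                draws = _draw_logistic(X_obs, y_obs, X_mis, rng)
            else:
                draws = _draw_pmm(X_obs, y_obs, X_mis, pmm_donors, rng)
            filled[rows_mis, j] = draws
    assert not np.isnan(filled).any()
    return filled


def _draw_logistic(X_obs, y_obs, X_mis, rng):
    classes = np.unique(y_obs)
    if len(classes) == 1:  # degenerate conditional: observed column constant
        return np.full(len(X_mis), classes[0])
    clf = LogisticRegression(C=_LOGISTIC_C, max_iter=1000)
    clf.fit(X_obs, y_obs)
    prob1 = clf.predict_proba(X_mis)[:, list(clf.classes_).index(1.0)]
    return (rng.random(len(X_mis)) < prob1).astype(float)


def _draw_pmm(X_obs, y_obs, X_mis, donors, rng):
    X1_obs = np.column_stack([np.ones(len(X_obs)), X_obs])
    X1_mis = np.column_stack([np.ones(len(X_mis)), X_mis])
    beta, *_ = np.linalg.lstsq(X1_obs, y_obs, rcond=None)
    pred_obs = X1_obs @ beta
    pred_mis = X1_mis @ beta
    k = min(donors, len(y_obs))
    out = np.empty(len(X_mis))
    for t, pm in enumerate(pred_mis):
        nearest = np.argsort(np.abs(pred_obs - pm), kind="stable")[:k]
        out[t] = y_obs[rng.choice(nearest)]
    return out
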