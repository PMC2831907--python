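"""Marginal and conditional independence tests for binary variables.

These are the decision engine of the PC search: Fisher's exact test for
marginal independence of two 0/1 variables, and a permutation test for
conditional independence given a set of binary conditioning variables.

The conditional statistic is the sum, over the ``2^|S|`` strata defined by
the conditioning set, of the Pearson chi-square of the stratum's 2x2 table;
strata with a zero row or column margin carry no information and contribute
0.  The null distribution permutes x within each stratum.  Given the stratum
margins, the permuted table is determined by its (1,1) cell, which under
uniform within-stratum permutation is hypergeometric — so the permutation
null is simulated exactly by vectorised hypergeometric draws rather than by
physically shuffling rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_N_PERM = 499
DEFAULT_MAX_COND_SIZE = 3


@dataclass
class CiResult:
    """Outcome of one independence test."""

    p_value: float
    statistic: float
    n_effective: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


def _as_binary(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("values must be binary 0/1 with no missing entries")
    return arr.astype(np.int8)


def contingency_2x2(x, y) -> np.ndarray:
    """Counts [[n00, n01], [n10, n11]] of two binary vectors."""
    x, y = _as_binary(x), _as_binary(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum(x == 1)) - n11
    n01 = int(np.sum(y == 1)) - n11
    n00 = len(x) - n11 - n10 - n01
    return np.array([[n00, n01], [n10, n11]])


def fisher_exact_binary(x, y) -> CiResult:
    """Two-sided Fisher exact test of the 2x2 table of x and y.

    The p-value sums the hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed that of the observed
    table.  A constant x or y gives a degenerate result with p = 1.
    """
    table = contingency_2x2(x, y)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return CiResult(1.0, 0.0, int(table.sum()), degenerate=True)
    res = stats.fisher_exact(table, alternative="two-sided")
    return CiResult(min(1.0, float(res.pvalue)), float(res.statistic),
                    int(table.sum()))


def _stratum_chi2(n11, n, r, c):
    """Pearson chi-square of a 2x2 table from its (1,1) cell and margins.

    Vectorised over ``n11``; margins with a zero row or column give 0.
    """
    n11 = np.asarray(n11, dtype=float)
    denom = float(r) * (n - r) * c * (n - c)
    if denom == 0:
        return np.zeros_like(n11)
    n10 = r - n11
    n01 = c - n11
    n00 = n - r - c + n11
    return n * (n11 * n00 - n10 * n01) ** 2 / denom


def permutation_ci_test(
    x,
    y,
    S=(),
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> CiResult:
    """Permutation test of ``x independent of y`` given binary vectors ``S``.

    Rows are stratified by the joint configuration of the conditioning
    vectors; the statistic sums the per-stratum Pearson chi-squares.  The
    permutation p-value uses the add-one rule
    ``(1 + #{null >= observed}) / (n_perm + 1)`` and is therefore never 0.
    """
    x, y = _as_binary(x), _as_binary(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    cond = [_as_binary(s) for s in S]
    if any(len(s) != len(x) for s in cond):
        raise ValueError("conditioning vectors must match x in length")

    # integer-encode the stratum of every row
    strata = np.zeros(len(x), dtype=np.int64)
    for s in cond:
        strata = strata * 2 + s
    labels = np.unique(strata)

    rng = np.random.default_rng(seed)
    observed = 0.0
    null = np.zeros(n_perm)
    informative = 0
    n_effective = 0
    for lab in labels:
        rows = strata == lab
        xs, ys = x[rows], y[rows]
        n = len(xs)
        r = int(xs.sum())
        c = int(ys.sum())
        if r in (0, n) or c in (0, n):
            continue  # zero margin: no information under permutation
        informative += 1
        n_effective += n
        n11 = int(np.sum((xs == 1) & (ys == 1)))
        observed += float(_stratum_chi2(n11, n, r, c))
        # permuting x within the stratum makes n11 hypergeometric given margins
        draws = rng.hypergeometric(c, n - c, r, size=n_perm)
        null += _stratum_chi2(draws, n, r, c)

    if informative == 0:
        return CiResult(1.0, 0.0, 0, degenerate=True)
    exceed = int(np.sum(null >= observed - 1e-12))
    p = (1 + exceed) / (n_perm + 1)
    return CiResult(p, observed, n_effective)
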