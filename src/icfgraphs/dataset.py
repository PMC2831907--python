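"""Tabular containers for ICF functioning data.

Two containers cover the pipeline's life cycle: :class:`RawDataset` holds
ordinal ICF qualifiers as collected (0-4 for the b/d/s components, -4..4 for
environmental factors), :class:`IcfDataset` holds the dichotomized 0/1 matrix
plus an optional continuous outcome column (the SF-36 General Health
Perception score, ``ghp``, on a 0-100 scale).  Both are thin wrappers around a
pandas DataFrame with float cells; missing entries are ``NaN``.

Column names are ICF-style codes: a component letter in ``{b, d, s, e}``
followed by digits, e.g. ``b152`` (emotional functions) or ``d450`` (walking).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CODE_PATTERN = re.compile(r"^[bdse]\d+$")

#: legal qualifier ranges per ICF component letter
QUALIFIER_RANGES: dict[str, tuple[int, int]] = {
    "b": (0, 4),
    "d": (0, 4),
    "s": (0, 4),
    "e": (-4, 4),
}

OUTCOME_COLUMN = "ghp"


class DatasetError(ValueError):
    """Raised for malformed datasets (bad codes, illegal qualifiers, ...)."""


def validate_codes(codes) -> list[str]:
    codes = [str(c) for c in codes]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise DatasetError(f"duplicate category codes: {dupes}")
    bad = [c for c in codes if not CODE_PATTERN.match(c)]
    if bad:
        raise DatasetError(f"codes must match component letter + digits: {bad}")
    return codes


@dataclass
class RawDataset:
    """Patients x categories matrix of ordinal ICF qualifiers with missing cells."""

    values: pd.DataFrame
    outcome: pd.Series | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        validate_codes(self.values.columns)
        self.values = self.values.astype(float)
        for code in self.values.columns:
            lo, hi = QUALIFIER_RANGES[code[0]]
            col = self.values[code]
            obs = col[col.notna()]
            bad = obs[(obs < lo) | (obs > hi) | (obs != np.round(obs))]
            if len(bad):
                row = int(bad.index[0])
                raise DatasetError(
                    f"illegal qualifier {bad.iloc[0]!r} for {code} at row {row}; "
                    f"legal range is {lo}..{hi}"
                )
        _check_outcome(self.outcome, len(self.values))

    @property
    def codes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class IcfDataset:
    """Patients x categories matrix over {0, 1, missing} with optional outcome.

    ``values`` is float-typed with NaN marking missing cells; every observed
    cell is 0.0 or 1.0 (1 = any impairment/limitation for b/d/s categories,
    facilitator for e categories).  ``outcome``, when present, is a complete
    numeric vector aligned with the rows.
    """

    values: pd.DataFrame
    outcome: pd.Series | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        validate_codes(self.values.columns)
        self.values = self.values.astype(float)
        arr = self.values.to_numpy()
        obs = arr[~np.isnan(arr)]
        if obs.size and not np.isin(obs, (0.0, 1.0)).all():
            raise DatasetError("binary dataset cells must be 0, 1 or missing")
        _check_outcome(self.outcome, len(self.values))

    @property
    def codes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-column fraction of missing cells."""
        return self.values.isna().mean()

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def copy(self) -> "IcfDataset":
        out = None if self.outcome is None else self.outcome.copy()
        return IcfDataset(self.values.copy(), out, self.provenance)

    def equals(self, other: "IcfDataset") -> bool:
        same_vals = self.values.equals(other.values)
        if self.outcome is None or other.outcome is None:
            return same_vals and (self.outcome is None) == (other.outcome is None)
        return same_vals and self.outcome.equals(other.outcome)


def _check_outcome(outcome: pd.Series | None, n: int) -> None:
    if outcome is None:
        return
    if len(outcome) != n:
        raise DatasetError("outcome length does not match row count")
    if outcome.isna().any():
        raise DatasetError("outcome must not contain missing values")


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def read_dataset(
    path: str | Path,
    kind: str = "auto",
    sep: str = ",",
    na_values: tuple[str, ...] = ("", "NA"),
) -> RawDataset | IcfDataset:
    """Read a delimited-text dataset (header row = ICF codes, optional ``ghp``).

    ``kind`` selects the container: ``"raw"`` (ordinal qualifiers),
    ``"binary"`` (0/1), or ``"auto"`` which returns an :class:`IcfDataset`
    when every observed category cell is 0/1 and a :class:`RawDataset`
    otherwise.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep=sep, na_values=list(na_values), keep_default_na=False,
            dtype=float,
        )
    except ValueError as exc:
        raise DatasetError(f"cannot parse {path}: {exc}") from exc
    header = list(pd.read_csv(path, sep=sep, nrows=0).columns)
    if len(set(header)) != len(header):
        raise DatasetError(f"duplicate column names in {path}")
    outcome = None
    if OUTCOME_COLUMN in frame.columns:
        outcome = frame.pop(OUTCOME_COLUMN)
        outcome.name = OUTCOME_COLUMN
    if kind == "auto":
        arr = frame.to_numpy()
        obs = arr[~np.isnan(arr)]
        kind = "binary" if np.isin(obs, (0.0, 1.0)).all() else "raw"
    cls = {"raw": RawDataset, "binary": IcfDataset}[kind]
    return cls(frame, outcome, provenance=str(path))


def write_dataset(
    data: RawDataset | IcfDataset, path: str | Path, sep: str = ","
) -> None:
    """Write a dataset as delimited text; missing cells become empty fields."""
    frame = data.values.copy()
    if data.outcome is not None:
        frame[OUTCOME_COLUMN] = data.outcome.to_numpy()
    frame.to_csv(path, sep=sep, index=False, na_rep="")
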