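"""Category filtering and dichotomization of raw ICF qualifiers.

The two preprocessing steps applied before any graph estimation:

* drop categories whose missing fraction exceeds a threshold (strictly
  greater than — a column sitting exactly at the threshold is kept), and
* collapse the ordinal qualifiers to 0/1: for body functions/structures and
  activities (b/d/s), 0 stays "no impairment/limitation" and grades 1-4
  become "any impairment/limitation"; for environmental factors (e),
  barrier-or-neutral grades (-4..0) map to 0 and facilitator grades (1-4)
  to 1.  Missing cells stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import QUALIFIER_RANGES, DatasetError, IcfDataset, RawDataset


@dataclass
class FilterReport:
    """Outcome of missingness filtering: what survived and what was dropped."""

    kept: list[str]
    dropped: list[str]
    missing_fraction: dict[str, float]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "kept": self.kept,
            "dropped": self.dropped,
            "missing_fraction": self.missing_fraction,
        }


def filter_missing_categories(
    data: RawDataset | IcfDataset, max_missing_fraction: float
):
    """Drop columns with *more than* ``max_missing_fraction`` missing cells.

    Returns ``(filtered_dataset, report)``; the filtered dataset is the same
    container type as the input.  A column at exactly the threshold is kept
    (strict "more than" semantics).
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = data.values.isna().mean()
    kept = [c for c in data.values.columns if frac[c] <= max_missing_fraction]
    dropped = [c for c in data.values.columns if c not in kept]
    report = FilterReport(
        kept=kept,
        dropped=dropped,
        missing_fraction={c: float(frac[c]) for c in data.values.columns},
        threshold=max_missing_fraction,
    )
    filtered = type(data)(
        data.values[kept].copy(),
        None if data.outcome is None else data.outcome.copy(),
        data.provenance,
    )
    return filtered, report


def dichotomize(raw: RawDataset) -> IcfDataset:
    """Collapse ordinal qualifiers to the binary impairment/facilitator coding."""
    values = raw.values.copy()
    for code in values.columns:
        lo, hi = QUALIFIER_RANGES[code[0]]
        col = values[code]
        obs = col[col.notna()]
        out_of_range = obs[(obs < lo) | (obs > hi)]
        if len(out_of_range):
            raise DatasetError(
                f"qualifier {out_of_range.iloc[0]!r} out of range for {code} "
                f"at row {int(out_of_range.index[0])}"
            )
        # b/d/s: any impairment (>=1) -> 1; e: facilitator (>=1) -> 1,
        # barrier/neutral (<=0) -> 0.  Both cases are "qualifier >= 1".
        values[code] = np.where(col.isna(), np.nan, (col >= 1).astype(float))
    return IcfDataset(
        values,
        None if raw.outcome is None else raw.outcome.copy(),
        provenance=raw.provenance,
    )
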