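"""Descriptive rate series and direct age standardization.

``series_by`` exports tidy (group, x, rate) tables for plotting rates by
age across periods or cohorts; ``age_adjust`` computes directly
standardized per-period rates against a :class:`StandardPopulation`.  The
WHO 2000 World Standard age weights ship with the package and can be
restricted/renormalized to any subset of 5-year groups (e.g. 40-44 … 85+).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ApcError
from .table import AgePeriodTable, _parse_interval

__all__ = ["StandardPopulation", "series_by", "age_adjust", "who2000_standard"]


@dataclass
class StandardPopulation:
    """Age-group weights for direct standardization (normalized to sum 1)."""

    age_labels: tuple[str, ...]
    weights: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.age_labels = tuple(str(a) for a in self.age_labels)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.age_labels),):
            raise ApcError("standard population weights/labels length mismatch")
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ApcError("standard population weights must be finite and >= 0")
        total = self.weights.sum()
        if total <= 0:
            raise ApcError("standard population weights must not all be zero")
        self.weights = self.weights / total

    @classmethod
    def from_csv(cls, path, name: str = "custom") -> "StandardPopulation":
        df = pd.read_csv(path)
        if not {"age_label", "weight"}.issubset(df.columns):
            raise ApcError("standard population CSV needs columns age_label, weight")
        return cls(tuple(df["age_label"].astype(str)), df["weight"].to_numpy(), name)


def _who2000_frame() -> pd.DataFrame:
    ref = resources.files(__package__) / "data" / "who2000.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def who2000_standard(age_labels) -> StandardPopulation:
    """WHO 2000 World Standard weights matched to the given age groups.

    Labels are matched on the parsed lower age bound (so '40-44' and
    '40–44' both match) and the selected weights are renormalized to sum
    to 1 over exactly those groups.
    """
    df = _who2000_frame()
    by_start = {}
    for lab, w in zip(df["age_label"], df["weight"]):
        parsed = _parse_interval(str(lab))
        by_start[parsed[0]] = float(w)
    weights = []
    for lab in age_labels:
        parsed = _parse_interval(str(lab))
        if parsed is None or parsed[0] not in by_start:
            raise ApcError(
                f"age group {lab!r} has no WHO 2000 standard weight "
                "(expected 5-year groups between 0-4 and 85+)"
            )
        weights.append(by_start[parsed[0]])
    return StandardPopulation(tuple(str(a) for a in age_labels), np.array(weights), "who2000")


def series_by(table: AgePeriodTable, axis: str = "period") -> pd.DataFrame:
    """Tidy rate series: one row per cell, grouped for plotting.

    ``axis='period'``: group = age label, x = period (rates by age across
    periods).  ``axis='age'``: group = period, x = age.  ``axis='cohort'``:
    group = age label, x = mid-cohort label (rates by age across cohorts).
    """
    long = table.to_long()
    if axis == "period":
        out = long.rename(columns={"age": "group", "period": "x"})
    elif axis == "age":
        out = long.rename(columns={"period": "group", "age": "x"})
        out = out[["group", "x", "rate"]]
    elif axis == "cohort":
        idx = table.cohort_index
        I = table.n_ages
        ii = np.repeat(np.arange(1, I + 1), table.n_periods)
        jj = np.tile(np.arange(1, table.n_periods + 1), I)
        out = pd.DataFrame(
            {
                "group": long["age"],
                "x": [idx.label_of(int(j - i + I)) for i, j in zip(ii, jj)],
                "rate": long["rate"],
            }
        )
    else:
        raise ApcError(f"unknown axis {axis!r}; use 'age', 'period' or 'cohort'")
    return out[["group", "x", "rate"]]


def age_adjust(table: AgePeriodTable, std: StandardPopulation) -> pd.DataFrame:
    """Directly standardized rate per period: sum_i w_i * rate_ij.

    The standard's age labels must match the table's, in order.
    """
    if std.age_labels != table.age_labels:
        raise ApcError(
            "standard population age groups do not match the table: "
            f"{std.age_labels} vs {table.age_labels}"
        )
    adjusted = std.weights @ table.rates
    return pd.DataFrame(
        {"period": list(table.period_labels), "adjusted_rate": adjusted}
    )
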