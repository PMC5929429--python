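"""Age x period contingency tables of event rates.

The central data structure is :class:`AgePeriodTable`: an I x J matrix of
event rates per 100,000 person-years indexed by ordered age-group and
calendar-period labels, optionally carrying matching matrices of event
counts (deaths) and person-time.  Cells are assigned to birth cohorts along
anti-diagonals: cell ``(i, j)`` (1-based) belongs to cohort ``k = j - i + I``,
so a table has ``K = I + J - 1`` cohorts.  Cohort 1 is the oldest-age,
earliest-period corner; cohort K the youngest-age, latest-period corner.

Tables are read and written as CSV in two dialects:

* ``wide`` — first column age labels, header row period labels, body rates;
* ``long`` — columns ``age, period, rate`` and optionally ``deaths,
  population``, one row per cell.

Two fixtures are packaged: ``hcc_males`` and ``hcc_females``, the printed
Taiwan 1976-2010 hepatocellular-carcinoma mortality tables (10 five-year age
groups from 40-44 to 85+, 7 five-year periods, 16 cohorts).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import TableError

__all__ = [
    "AgePeriodTable",
    "CohortIndex",
    "read_table",
    "write_table",
    "load_fixture",
    "available_fixtures",
    "cohort_of_cell",
    "cells_of_cohort",
]

RATE_SCALE = 100_000.0

_RANGE_RE = re.compile(r"^\s*(\d+)\s*[–—-]\s*(\d+)\s*$")
_OPEN_RE = re.compile(r"^\s*(\d+)\s*\+\s*$")

_FIXTURES = {
    "hcc_males": "hcc_males.csv",
    "hcc_females": "hcc_females.csv",
}


def _parse_interval(label: str) -> tuple[int, int | None] | None:
    """Return (start, end) for '40–44', (start, None) for '85+', else None."""
    m = _RANGE_RE.match(label)
    if m:
        return int(m.group(1)), int(m.group(2))
    m = _OPEN_RE.match(label)
    if m:
        return int(m.group(1)), None
    return None


@dataclass(frozen=True)
class CohortIndex:
    """Anti-diagonal cohort indexing of an I x J table.

    ``cohort_labels[k-1]`` is the mid-cohort year of cohort ``k`` (period
    midpoint minus age-group midpoint, on the common interval grid) when the
    table labels parse as numeric intervals, otherwise the generic label
    ``"C<k>"``.
    """

    n_ages: int
    n_periods: int
    cohort_labels: tuple[object, ...]

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1

    def cohort_of(self, i: int, j: int) -> int:
        if not (1 <= i <= self.n_ages and 1 <= j <= self.n_periods):
            raise TableError(
                f"cell index (i={i}, j={j}) outside 1..{self.n_ages} x 1..{self.n_periods}"
            )
        return j - i + self.n_ages

    def cells_of(self, k: int) -> list[tuple[int, int]]:
        if not (1 <= k <= self.n_cohorts):
            raise TableError(f"cohort index k={k} outside 1..{self.n_cohorts}")
        return [
            (j - k + self.n_ages, j)
            for j in range(max(1, k - self.n_ages + 1), min(self.n_periods, k) + 1)
        ]

    def label_of(self, k: int) -> object:
        if not (1 <= k <= self.n_cohorts):
            raise TableError(f"cohort index k={k} outside 1..{self.n_cohorts}")
        return self.cohort_labels[k - 1]

    def cell_matrix(self) -> np.ndarray:
        """I x J integer matrix of cohort indices k = j - i + I."""
        i = np.arange(1, self.n_ages + 1)[:, None]
        j = np.arange(1, self.n_periods + 1)[None, :]
        return j - i + self.n_ages


def _cohort_labels(
    age_labels: Sequence[str], period_labels: Sequence[str]
) -> tuple[object, ...]:
    """Mid-cohort year per anti-diagonal, or generic labels if unparsable.

    Requires equal interval widths for age and period; the open-ended last
    age group is treated as a nominal interval of the common width.
    """
    I, J = len(age_labels), len(period_labels)
    K = I + J - 1
    ages = [_parse_interval(a) for a in age_labels]
    periods = [_parse_interval(p) for p in period_labels]
    if any(a is None for a in ages) or any(
        p is None or p[1] is None for p in periods
    ):
        return tuple(f"C{k}" for k in range(1, K + 1))

    widths = {p[1] - p[0] + 1 for p in periods}
    widths |= {a[1] - a[0] + 1 for a in ages if a[1] is not None}
    if len(widths) != 1:
        raise TableError(
            "unequal age/period interval widths; cohort indexing requires a "
            f"single common width, got {sorted(widths)}"
        )
    w = widths.pop()
    for seq, kind in ((ages, "age"), (periods, "period")):
        starts = [s[0] for s in seq]
        if any(b - a != w for a, b in zip(starts, starts[1:])):
            raise TableError(f"{kind} labels are not contiguous {w}-year intervals")

    # Anchor on the first (closed) age group; open-ended groups inherit the
    # grid by arithmetic extension, which reproduces printed mid-cohort years.
    age_mid = ages[0][0] + (w - 1) / 2
    period_mid = periods[0][0] + (w - 1) / 2
    base = period_mid - age_mid  # label of cohort k = 1 - 1 + I = I
    labels = [base + w * (k - I) for k in range(1, K + 1)]
    return tuple(int(x) if float(x).is_integer() else x for x in labels)


@dataclass
class AgePeriodTable:
    """An age x period table of rates per 100,000, with optional counts.

    Parameters
    ----------
    age_labels, period_labels
        Ordered row/column labels.
    rates
        I x J strictly positive rates per 100,000 person-years.
    deaths
        Optional I x J non-negative event counts.
    population
        Optional I x J strictly positive person-time.
    meta
        Free-text tags (sex, cause, source, ...).
    check_consistency
        When deaths and population are both present, verify
        ``rates == deaths / population * 100000`` to relative 1e-6.
    """

    age_labels: tuple[str, ...]
    period_labels: tuple[str, ...]
    rates: np.ndarray
    deaths: np.ndarray | None = None
    population: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    check_consistency: bool = True

    def __post_init__(self) -> None:
        self.age_labels = tuple(str(a) for a in self.age_labels)
        self.period_labels = tuple(str(p) for p in self.period_labels)
        self.rates = np.asarray(self.rates, dtype=float)
        I, J = len(self.age_labels), len(self.period_labels)
        if I < 2 or J < 2:
            raise TableError(f"need at least 2 age groups and 2 periods, got {I}x{J}")
        if self.rates.shape != (I, J):
            raise TableError(
                f"rates shape {self.rates.shape} does not match labels ({I}, {J})"
            )
        bad = ~(np.isfinite(self.rates) & (self.rates > 0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise TableError(
                "non-positive rate at cell "
                f"(age={self.age_labels[i]}, period={self.period_labels[j]}): "
                f"{self.rates[i, j]!r}; log transform requires rates > 0"
            )
        if self.deaths is not None:
            self.deaths = np.asarray(self.deaths, dtype=float)
            if self.deaths.shape != (I, J):
                raise TableError("deaths matrix shape mismatch")
            if not np.all(np.isfinite(self.deaths) & (self.deaths >= 0)):
                raise TableError("deaths must be finite and >= 0")
        if self.population is not None:
            self.population = np.asarray(self.population, dtype=float)
            if self.population.shape != (I, J):
                raise TableError("population matrix shape mismatch")
            if not np.all(np.isfinite(self.population) & (self.population > 0)):
                raise TableError("population must be finite and > 0")
        if (
            self.check_consistency
            and self.deaths is not None
            and self.population is not None
        ):
            implied = self.deaths / self.population * RATE_SCALE
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(implied - self.rates) / np.abs(self.rates)
            if np.nanmax(rel) > 1e-6:
                i, j = map(int, np.argwhere(rel > 1e-6)[0])
                raise TableError(
                    "rates inconsistent with deaths/population at cell "
                    f"(age={self.age_labels[i]}, period={self.period_labels[j]}): "
                    f"rate={self.rates[i, j]} vs implied={implied[i, j]:.6f}"
                )
        self._cohort_index = CohortIndex(
            n_ages=I,
            n_periods=J,
            cohort_labels=_cohort_labels(self.age_labels, self.period_labels),
        )

    # -- shape ----------------------------------------------------------
    @property
    def n_ages(self) -> int:
        return len(self.age_labels)

    @property
    def n_periods(self) -> int:
        return len(self.period_labels)

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1

    @property
    def cohort_index(self) -> CohortIndex:
        return self._cohort_index

    def log_rates(self) -> np.ndarray:
        """Natural log of the rate per person-year, ``log(rate / 100000)``."""
        return np.log(self.rates / RATE_SCALE)

    # -- frames ---------------------------------------------------------
    def to_wide(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.rates, index=list(self.age_labels), columns=list(self.period_labels)
        )
        df.index.name = "age"
        return df

    def to_long(self) -> pd.DataFrame:
        I, J = self.n_ages, self.n_periods
        ii, jj = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
        out = pd.DataFrame(
            {
                "age": [self.age_labels[i] for i in ii.ravel()],
                "period": [self.period_labels[j] for j in jj.ravel()],
                "rate": self.rates.ravel(),
            }
        )
        if self.deaths is not None:
            out["deaths"] = self.deaths.ravel()
        if self.population is not None:
            out["population"] = self.population.ravel()
        return out


def cohort_of_cell(table: AgePeriodTable, i: int, j: int) -> tuple[int, object]:
    """Cohort index ``k = j - i + I`` and mid-cohort label for 1-based (i, j)."""
    k = table.cohort_index.cohort_of(i, j)
    return k, table.cohort_index.label_of(k)


def cells_of_cohort(table: AgePeriodTable, k: int) -> list[tuple[int, int]]:
    """All 1-based cells on anti-diagonal ``k``, ordered by increasing period."""
    return table.cohort_index.cells_of(k)


def read_table(path, layout: str = "wide", **kwargs) -> AgePeriodTable:
    """Read an :class:`AgePeriodTable` from CSV.

    ``layout='wide'``: first column age labels, header periods, cells rates.
    ``layout='long'``: columns ``age, period, rate[, deaths, population]``.
    Label order follows first appearance in the file.
    """
    if layout == "wide":
        df = pd.read_csv(path, index_col=0, dtype=str)

        def _to_float(v):
            # float() is exactly rounding; pd.to_numeric's parser is not
            try:
                return float(v)
            except (TypeError, ValueError):
                return np.nan

        rates = df.apply(lambda col: col.map(_to_float)).to_numpy()
        if np.isnan(rates).any():
            i, j = map(int, np.argwhere(np.isnan(rates))[0])
            raise TableError(
                f"missing or non-numeric rate at cell (age={df.index[i]}, "
                f"period={df.columns[j]})"
            )
        return AgePeriodTable(
            age_labels=tuple(df.index),
            period_labels=tuple(df.columns),
            rates=rates,
            **kwargs,
        )
    if layout == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"age", "period", "rate"}
        if not required.issubset(df.columns):
            raise TableError(
                f"long layout requires columns {sorted(required)}, got {list(df.columns)}"
            )
        ages = list(dict.fromkeys(df["age"].astype(str)))
        periods = list(dict.fromkeys(df["period"].astype(str)))
        if len(df) != len(ages) * len(periods):
            raise TableError(
                f"long table has {len(df)} rows; expected "
                f"{len(ages)}x{len(periods)} = {len(ages) * len(periods)} "
                "(one per cell)"
            )
        ai = {a: n for n, a in enumerate(ages)}
        pj = {p: n for n, p in enumerate(periods)}

        def pivot(col):
            m = np.full((len(ages), len(periods)), np.nan)
            for _, row in df.iterrows():
                m[ai[str(row["age"])], pj[str(row["period"])]] = row[col]
            return m

        rates = pivot("rate")
        if np.isnan(rates).any():
            raise TableError("long table does not cover every (age, period) cell")
        deaths = pivot("deaths") if "deaths" in df.columns else None
        population = pivot("population") if "population" in df.columns else None
        return AgePeriodTable(
            age_labels=tuple(ages),
            period_labels=tuple(periods),
            rates=rates,
            deaths=deaths,
            population=population,
            **kwargs,
        )
    raise TableError(f"unknown layout {layout!r}; use 'wide' or 'long'")


def write_table(table: AgePeriodTable, path, layout: str = "wide") -> None:
    """Write a table to CSV in the given layout (full float precision)."""
    if layout == "wide":
        table.to_wide().to_csv(path, float_format="%.17g")
    elif layout == "long":
        table.to_long().to_csv(path, index=False, float_format="%.17g")
    else:
        raise TableError(f"unknown layout {layout!r}; use 'wide' or 'long'")


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str) -> AgePeriodTable:
    """Load a packaged rate table (``hcc_males`` or ``hcc_females``)."""
    if name not in _FIXTURES:
        raise TableError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        )
    ref = resources.files(__package__) / "data" / _FIXTURES[name]
    with resources.as_file(ref) as p:
        table = read_table(p, layout="wide")
    table.meta.update({"fixture": name, "sex": name.split("_")[1]})
    return table
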