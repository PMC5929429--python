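"""Automatic choice of the referent birth cohort.

The referent cohort is the one whose rates change least when the cohort
influence is removed.  Removing the cohort influence multiplies each cell's
rate by ``exp(-residual)``; per cohort, the ratio of cohort-free to
observed rate aggregated as a geometric mean over its cells is
``exp(-mean residual)``, so the cohort with mean residual closest to zero
is selected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EstimationError
from .polish import MedianPolishDecomposition
from .table import RATE_SCALE, AgePeriodTable

__all__ = ["rates_without_cohort", "select_reference"]


def rates_without_cohort(
    table: AgePeriodTable, dec: MedianPolishDecomposition
) -> np.ndarray:
    """Cell-wise rates with the cohort influence removed: rate * exp(-residual)."""
    if dec.residuals.shape != table.rates.shape:
        raise EstimationError(
            f"decomposition residuals {dec.residuals.shape} do not match "
            f"table shape {table.rates.shape}"
        )
    return table.rates * np.exp(-dec.residuals)


def select_reference(
    table: AgePeriodTable, dec: MedianPolishDecomposition
) -> tuple[int, pd.DataFrame]:
    """Pick the referent cohort and return diagnostics for all cohorts.

    Per cohort the ratio of cohort-free to observed rates (geometric mean
    over cells) is ``exp(-mean residual)``.  The cohort minimizing
    ``|log ratio|`` wins; exact ties are broken by more supporting cells,
    then by later mid-cohort position.  The diagnostics frame lists every
    cohort sorted by closeness to ratio 1.
    """
    without = rates_without_cohort(table, dec)
    idx = table.cohort_index
    kmat = idx.cell_matrix()
    K = table.n_cohorts
    ratio = np.empty(K)
    n_cells = np.empty(K, dtype=int)
    for k in range(1, K + 1):
        sel = kmat == k
        n_cells[k - 1] = sel.sum()
        ratio[k - 1] = np.exp(np.mean(np.log(without[sel] / table.rates[sel])))
    abs_log = np.abs(np.log(ratio))
    best = abs_log.min()
    candidates = np.flatnonzero(abs_log <= best + 1e-12)
    # tie-breaks: more cells, then later cohort
    order = sorted(candidates, key=lambda c: (-n_cells[c], -c))
    k_sel = int(order[0]) + 1
    diag = pd.DataFrame(
        {
            "k": np.arange(1, K + 1),
            "cohort": list(idx.cohort_labels),
            "ratio": ratio,
            "abs_log_ratio": abs_log,
            "n_cells": n_cells,
            "selected": np.arange(1, K + 1) == k_sel,
        }
    ).sort_values(["abs_log_ratio", "k"], kind="stable", ignore_index=True)
    return k_sel, diag
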