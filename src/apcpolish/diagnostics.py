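"""Poisson deviance diagnostics for the nested model sequence.

For tables carrying death counts and person-time, expected counts under
the progressively richer fits — null, age, age-period, and full APC —
are compared to observed counts via Poisson deviance residuals

    d = sign(O - E) * sqrt(2 * (O * log(O / E) - (O - E)))

with the ``O log(O/E)`` term taken as 0 when ``O = 0``.  The sum of squared
deviance residuals should shrink as terms are added.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohorts import CohortEffectEstimates
from .errors import ApcError
from .polish import MedianPolishDecomposition
from .table import AgePeriodTable

__all__ = ["MODELS", "fitted_deaths", "deviance_residuals", "deviance_summary"]

MODELS = ("null", "age", "age_period", "apc")


def fitted_deaths(
    table: AgePeriodTable,
    dec: MedianPolishDecomposition,
    est: CohortEffectEstimates | None = None,
    model: str = "apc",
) -> np.ndarray:
    """Expected counts E_ij = population_ij * exp(fitted log rate).

    The fitted log rate accumulates terms by model: ``mu`` (null),
    ``+ alpha_i`` (age), ``+ beta_j`` (age_period), ``+ gamma_k`` (apc,
    needs cohort estimates).
    """
    if model not in MODELS:
        raise ApcError(f"unknown model {model!r}; choose from {MODELS}")
    if table.population is None:
        raise ApcError("fitted_deaths needs a population matrix on the table")
    I, J = table.n_ages, table.n_periods
    log_rate = np.full((I, J), dec.mu)
    if model in ("age", "age_period", "apc"):
        log_rate += dec.alpha[:, None]
    if model in ("age_period", "apc"):
        log_rate += dec.beta[None, :]
    if model == "apc":
        if est is None:
            raise ApcError("apc model needs cohort-effect estimates")
        kmat = table.cohort_index.cell_matrix()
        log_rate += est.gamma[kmat - 1]
    return table.population * np.exp(log_rate)


def deviance_residuals(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Signed Poisson deviance residual per cell."""
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if O.shape != E.shape:
        raise ApcError("observed and expected shapes differ")
    if np.any(E <= 0) or not np.all(np.isfinite(E)):
        raise ApcError("expected counts must be finite and > 0")
    if np.any(O < 0) or not np.all(np.isfinite(O)):
        raise ApcError("observed counts must be finite and >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        olog = np.where(O > 0, O * np.log(np.where(O > 0, O, 1.0) / E), 0.0)
    inner = 2.0 * (olog - (O - E))
    return np.sign(O - E) * np.sqrt(np.maximum(inner, 0.0))


def deviance_summary(
    table: AgePeriodTable,
    dec: MedianPolishDecomposition,
    est: CohortEffectEstimates | None = None,
) -> pd.DataFrame:
    """Sum of squared deviance residuals for each nested model.

    The ``apc`` row is included only when cohort estimates are supplied.
    Needs both deaths and population on the table.
    """
    if table.deaths is None or table.population is None:
        raise ApcError("deviance_summary needs deaths and population matrices")
    rows = []
    for model in MODELS:
        if model == "apc" and est is None:
            continue
        E = fitted_deaths(table, dec, est=est, model=model)
        d = deviance_residuals(table.deaths, E)
        rows.append({"model": model, "deviance": float((d**2).sum())})
    return pd.DataFrame(rows)
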