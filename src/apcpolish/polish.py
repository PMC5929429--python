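"""Median polish of log rates: remove additive age and period effects.

The decomposition of the log rate per person-year is

    log(rate_ij / 100000) = mu + alpha_i + beta_j + residual_ij

obtained by iteratively subtracting row medians and column medians (rows
first within each sweep, Tukey's convention).  The residual matrix carries
whatever systematic structure is not additive in age and period — in this
pipeline, the cohort signal picked up downstream.

The reconstruction identity above holds exactly (by construction) after
every sweep; convergence means every row and column median of the residuals
is below ``tol`` in absolute value.

Centering of the effect vectors is a reporting convention and does not
touch the residuals.  The default ``centering='mean'`` folds the means of
``alpha`` and ``beta`` into ``mu`` so the effects sum to zero, matching the
usual sum-to-zero APC constraint; ``centering='median'`` makes the effect
medians zero instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ApcError
from .table import RATE_SCALE, AgePeriodTable
from .utils import round_half_up

__all__ = ["MedianPolishDecomposition", "median_polish", "polish_matrix", "polish_summary"]


@dataclass
class MedianPolishDecomposition:
    """Additive two-way decomposition of a log-rate matrix.

    ``mu + alpha[i] + beta[j] + residuals[i, j]`` reproduces the input
    log rate (per person-year) for every cell.
    """

    mu: float
    alpha: np.ndarray
    beta: np.ndarray
    residuals: np.ndarray
    n_iterations: int
    converged: bool
    centering: str = "mean"
    age_labels: tuple[str, ...] = ()
    period_labels: tuple[str, ...] = ()

    def fitted_log_rates(self) -> np.ndarray:
        """Cohort-free fit: mu + alpha_i + beta_j per cell."""
        return self.mu + self.alpha[:, None] + self.beta[None, :]

    def reconstruct_log_rates(self) -> np.ndarray:
        return self.fitted_log_rates() + self.residuals

    def to_long(self) -> pd.DataFrame:
        """Long-form (component, label, value) export, unrounded."""
        rows = [("constant", "", self.mu)]
        rows += [
            ("period", lab, v)
            for lab, v in zip(self.period_labels or [str(j + 1) for j in range(len(self.beta))], self.beta)
        ]
        rows += [
            ("age", lab, v)
            for lab, v in zip(self.age_labels or [str(i + 1) for i in range(len(self.alpha))], self.alpha)
        ]
        return pd.DataFrame(rows, columns=["component", "label", "value"])


def polish_matrix(
    x: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    centering: str = "mean",
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, int, bool]:
    """Median-polish an arbitrary matrix.

    Returns ``(mu, row_effects, col_effects, residuals, n_iterations,
    converged)``.  Each iteration subtracts row medians then column medians;
    iteration stops when the largest absolute row/column median of the
    residuals is <= ``tol``.  Effect vectors are centered per ``centering``
    with the offsets folded into ``mu``.
    """
    if max_iter < 1:
        raise ApcError("max_iter must be >= 1")
    if tol < 0:
        raise ApcError("tol must be >= 0")
    if centering not in ("mean", "median"):
        raise ApcError(f"unknown centering {centering!r}; use 'mean' or 'median'")
    r = np.array(x, dtype=float)
    if r.ndim != 2:
        raise ApcError("polish requires a 2-d matrix")
    I, J = r.shape
    mu = 0.0
    alpha = np.zeros(I)
    beta = np.zeros(J)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        row_med = np.median(r, axis=1)
        r -= row_med[:, None]
        alpha += row_med
        col_med = np.median(r, axis=0)
        r -= col_med[None, :]
        beta += col_med
        gap = max(
            np.abs(np.median(r, axis=1)).max(),
            np.abs(np.median(r, axis=0)).max(),
        )
        if gap <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"median polish did not converge in {max_iter} iterations "
            f"(residual row/col median gap {gap:.3g} > tol {tol:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    center = np.mean if centering == "mean" else np.median
    for vec in (alpha, beta):
        shift = center(vec)
        vec -= shift
        mu += shift
    return mu, alpha, beta, r, n_iter, converged


def median_polish(
    table: AgePeriodTable,
    max_iter: int = 100,
    tol: float = 1e-8,
    centering: str = "mean",
) -> MedianPolishDecomposition:
    """Decompose a table's log rates into overall, age, period effects + residuals."""
    mu, alpha, beta, resid, n_iter, converged = polish_matrix(
        table.log_rates(), max_iter=max_iter, tol=tol, centering=centering
    )
    return MedianPolishDecomposition(
        mu=mu,
        alpha=alpha,
        beta=beta,
        residuals=resid,
        n_iterations=n_iter,
        converged=converged,
        centering=centering,
        age_labels=table.age_labels,
        period_labels=table.period_labels,
    )


def polish_summary(dec: MedianPolishDecomposition, decimals: int = 2) -> pd.DataFrame:
    """Reporting table: constant, period and age effects, rounded half-up."""
    df = dec.to_long()
    df["effect"] = [round_half_up(v, decimals) for v in df["value"]]
    return df[["component", "label", "effect"]]


def rates_from_decomposition(dec: MedianPolishDecomposition) -> np.ndarray:
    """Back-transform ``exp(mu + alpha + beta + residual) * 100000``."""
    return np.exp(dec.reconstruct_log_rates()) * RATE_SCALE
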