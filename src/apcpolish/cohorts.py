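"""Cohort-effect estimation from median-polish residuals.

After the additive age and period effects are removed, each cell's residual
is modelled as the level of its birth cohort plus noise:

    residual_ijk = gamma_k + error_ijk

The design is a set of K cohort indicator columns with no intercept, so the
unweighted least-squares coefficients are exactly the per-cohort means of
the residuals.  Weighted estimation solves the same normal equations with
per-record observation weights (typically proportional to cell death
counts, so better-supported cells count for more); with uniform weights it
reproduces the unweighted fit identically.

Rate ratios against a reference cohort are ``exp(gamma_k - gamma_ref)``
with Wald confidence intervals from the fit's coefficient variances
(indicator groups are disjoint, so coefficient estimates are independent
and the variance of a difference is the sum of variances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError
from .polish import MedianPolishDecomposition
from .table import AgePeriodTable
from .utils import round_half_up

__all__ = [
    "ResidualObservations",
    "CohortEffectEstimates",
    "build_observations",
    "compute_weights",
    "fit_cohort_regression",
    "rate_ratios",
    "format_report",
]

WEIGHT_STRATEGIES = ("uniform", "per_cell_deaths", "per_cohort_deaths")


@dataclass
class ResidualObservations:
    """One record per table cell: indices, cohort, residual, optional deaths."""

    i: np.ndarray  # 1-based age index
    j: np.ndarray  # 1-based period index
    k: np.ndarray  # cohort index, k = j - i + I
    residual: np.ndarray
    deaths: np.ndarray | None
    n_cohorts: int
    cohort_labels: tuple[object, ...]

    def __len__(self) -> int:
        return len(self.residual)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "i": self.i,
                "j": self.j,
                "k": self.k,
                "cohort": [self.cohort_labels[k - 1] for k in self.k],
                "residual": self.residual,
            }
        )
        if self.deaths is not None:
            df["deaths"] = self.deaths
        return df


@dataclass
class CohortEffectEstimates:
    """Per-cohort regression results on the log-residual scale."""

    gamma: np.ndarray
    se: np.ndarray
    weights: np.ndarray  # per-cohort occupied proportion W_k, sums to 1
    n_cells: np.ndarray
    cohort_labels: tuple[object, ...]
    mode: str
    scale: float  # residual variance estimate of the fit
    df_resid: int

    @property
    def n_cohorts(self) -> int:
        return len(self.gamma)


def build_observations(
    dec: MedianPolishDecomposition, table: AgePeriodTable
) -> ResidualObservations:
    """Flatten a decomposition's residuals into per-cell records with cohorts."""
    I, J = table.n_ages, table.n_periods
    if dec.residuals.shape != (I, J):
        raise EstimationError(
            f"decomposition residuals {dec.residuals.shape} do not match "
            f"table shape ({I}, {J})"
        )
    ii, jj = np.meshgrid(np.arange(1, I + 1), np.arange(1, J + 1), indexing="ij")
    i, j = ii.ravel(), jj.ravel()
    return ResidualObservations(
        i=i,
        j=j,
        k=j - i + I,
        residual=dec.residuals.ravel(),
        deaths=None if table.deaths is None else table.deaths.ravel(),
        n_cohorts=table.n_cohorts,
        cohort_labels=table.cohort_index.cohort_labels,
    )


def compute_weights(obs: ResidualObservations, strategy: str = "uniform") -> np.ndarray:
    """Per-record observation weights, normalized to sum to 1.

    ``uniform``
        Every record 1/n.
    ``per_cell_deaths``
        w_ij = D_ij / sum(D): each cell's share of all deaths.
    ``per_cohort_deaths``
        W_k = (deaths in cohort k) / sum(D), replicated to each of the
        cohort's cells (so record weights sum to W_k * n_cells_k up to the
        final normalization).
    """
    n = len(obs)
    if strategy == "uniform":
        return np.full(n, 1.0 / n)
    if strategy not in WEIGHT_STRATEGIES:
        raise EstimationError(
            f"unknown weighting strategy {strategy!r}; choose from {WEIGHT_STRATEGIES}"
        )
    if obs.deaths is None:
        raise EstimationError(
            f"strategy {strategy!r} needs death counts, but the table has none"
        )
    total = obs.deaths.sum()
    if total <= 0:
        raise EstimationError("all death counts are zero; cannot form death weights")
    if strategy == "per_cell_deaths":
        w = obs.deaths / total
    else:  # per_cohort_deaths: W_k replicated to cells; sums to 1 over cohorts
        cohort_share = np.zeros(obs.n_cohorts)
        for k in range(1, obs.n_cohorts + 1):
            cohort_share[k - 1] = obs.deaths[obs.k == k].sum() / total
        w = cohort_share[obs.k - 1]
    cohort_tot = np.array([w[obs.k == k].sum() for k in range(1, obs.n_cohorts + 1)])
    if np.any(cohort_tot == 0):
        warnings.warn(
            "degenerate weights: at least one cohort carries zero total weight",
            RuntimeWarning,
            stacklevel=2,
        )
    return w


def fit_cohort_regression(
    obs: ResidualObservations,
    weights: np.ndarray | None = None,
    mode: str | None = None,
) -> CohortEffectEstimates:
    """Least-squares fit of residuals on cohort indicators (no intercept).

    Unweighted, the coefficient for cohort k is the arithmetic mean of its
    residuals.  With weights, the weighted normal equations give weighted
    group means; the variance estimate is the standard (W)LS one with
    weights normalized to sum to the record count and ``n - K`` residual
    degrees of freedom.
    """
    n, K = len(obs), obs.n_cohorts
    counts = np.array([(obs.k == k).sum() for k in range(1, K + 1)])
    if np.any(counts == 0):
        raise EstimationError("every cohort needs at least one record")
    if weights is None:
        w = np.ones(n)
        mode = mode or "unweighted"
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise EstimationError(f"weights must have shape ({n},), got {w.shape}")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise EstimationError("weights must be finite and non-negative")
        if w.sum() <= 0:
            raise EstimationError("weights must not all be zero")
        mode = mode or "weighted"
    # normalize so sum(w) = n: uniform weights then equal the OLS unit weights
    w = w * (n / w.sum())

    gamma = np.empty(K)
    wk = np.empty(K)
    for k in range(1, K + 1):
        sel = obs.k == k
        wk[k - 1] = w[sel].sum()
        if wk[k - 1] <= 0:
            raise EstimationError(
                f"cohort {obs.cohort_labels[k - 1]} has zero total weight; "
                "its effect is unidentifiable"
            )
        gamma[k - 1] = np.dot(w[sel], obs.residual[sel]) / wk[k - 1]
    fitted = gamma[obs.k - 1]
    df_resid = n - K
    rss = float(np.dot(w, (obs.residual - fitted) ** 2))
    scale = rss / df_resid if df_resid > 0 else 0.0
    se = np.sqrt(scale / wk)
    return CohortEffectEstimates(
        gamma=gamma,
        se=se,
        weights=wk / wk.sum(),
        n_cells=counts,
        cohort_labels=obs.cohort_labels,
        mode=mode,
        scale=scale,
        df_resid=df_resid,
    )


def rate_ratios(
    est: CohortEffectEstimates,
    k_ref: int,
    alpha_level: float = 0.05,
    use_t: bool = False,
) -> pd.DataFrame:
    """Rate ratios and CIs of every cohort against the reference cohort.

    Returns an unrounded frame with columns ``k, cohort, rr, ci_low,
    ci_high, se_diff, is_ref, mode``; the reference row has rr exactly 1 and
    NaN CI bounds.  ``use_t`` switches the Wald quantile from normal to
    Student t with the fit's residual degrees of freedom.
    """
    K = est.n_cohorts
    if not (1 <= k_ref <= K):
        raise EstimationError(f"reference cohort {k_ref} outside 1..{K}")
    if not (0 < alpha_level < 1):
        raise EstimationError("alpha_level must be in (0, 1)")
    if use_t:
        q = stats.t.ppf(1 - alpha_level / 2, est.df_resid)
    else:
        q = stats.norm.ppf(1 - alpha_level / 2)
    diff = est.gamma - est.gamma[k_ref - 1]
    se_diff = np.sqrt(est.se**2 + est.se[k_ref - 1] ** 2)
    rr = np.exp(diff)
    lo = np.exp(diff - q * se_diff)
    hi = np.exp(diff + q * se_diff)
    is_ref = np.arange(1, K + 1) == k_ref
    rr[is_ref] = 1.0
    se_diff[is_ref] = 0.0
    lo[is_ref] = np.nan
    hi[is_ref] = np.nan
    return pd.DataFrame(
        {
            "k": np.arange(1, K + 1),
            "cohort": list(est.cohort_labels),
            "rr": rr,
            "ci_low": lo,
            "ci_high": hi,
            "se_diff": se_diff,
            "is_ref": is_ref,
            "mode": est.mode,
        }
    )


def format_report(ratios: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Printable report mirroring the published table layout.

    Columns ``cohort, effect, ci_low, ci_high, mode``; the reference row
    shows effect 1.00 and CI bounds "REF".
    """
    out = pd.DataFrame(
        {
            "cohort": ratios["cohort"],
            "effect": [f"{round_half_up(v, decimals):.{decimals}f}" for v in ratios["rr"]],
            "ci_low": [
                "REF" if r else f"{round_half_up(v, decimals):.{decimals}f}"
                for r, v in zip(ratios["is_ref"], ratios["ci_low"])
            ],
            "ci_high": [
                "REF" if r else f"{round_half_up(v, decimals):.{decimals}f}"
                for r, v in zip(ratios["is_ref"], ratios["ci_high"])
            ],
            "mode": ratios["mode"],
        }
    )
    return out
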