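"""Cross-validated tuning of (gamma, rho) and the evaluation metrics.

Thin functional layer over the CV estimators in
:mod:`phyloglmm.estimators`.  The criterion is predicted mean squared
error (PMSE, minimized) for continuous outcomes and AUC (maximized) for
binary outcomes; prediction performance is summarized by the squared
sample correlation R^2 between observed and predicted values (predicted
probabilities for a binary outcome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .estimators import (
    DEFAULT_GAMMA_GRID,
    DEFAULT_RHO_GRID,
    FALLBACK_RHO,
    PhyloKernelClassifierCV,
    PhyloKernelRegressorCV,
)
from .tree import PhyloDistances


@dataclass
class TuningGrid:
    """Search grids and CV layout for the (gamma, rho) tuning pair."""

    rho_values: tuple = DEFAULT_RHO_GRID
    gamma_values: tuple = DEFAULT_GAMMA_GRID
    n_folds: int = 5
    criterion: str = "auto"  # "pmse" | "auc" | "auto"
    seed: int = 0
    append_fallback_rho: bool = True

    def __post_init__(self) -> None:
        if len(self.rho_values) == 0 or len(self.gamma_values) == 0:
            raise ValueError("grids must be non-empty")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class TuningResult:
    cv_table: pd.DataFrame = field(repr=False)
    best_gamma: float = 0.0
    best_rho: float = 0.0
    best_score: float = 0.0
    criterion: str = "pmse"
    final_model: object = None


def _is_binary(y: np.ndarray) -> bool:
    vals = np.unique(y)
    return len(vals) == 2


def cross_validate(
    y,
    Z,
    dist: PhyloDistances,
    covariates=None,
    grid: TuningGrid | None = None,
    squared_distance: bool = True,
) -> TuningResult:
    """Grid-search (gamma, rho) by k-fold CV and refit at the best cell.

    Binary outcomes use stratified folds and AUC; continuous outcomes use
    plain folds and PMSE.  Ties break toward the first optimum in
    row-major order (gamma ascending outer, rho ascending inner).
    """
    grid = grid or TuningGrid()
    y = np.asarray(y).ravel()
    criterion = grid.criterion
    if criterion == "auto":
        criterion = "auc" if _is_binary(y) else "pmse"
    cls = PhyloKernelClassifierCV if criterion == "auc" else PhyloKernelRegressorCV
    est = cls(
        distances=dist,
        rho_grid=list(grid.rho_values),
        gamma_grid=list(grid.gamma_values),
        n_folds=grid.n_folds,
        squared_distance=squared_distance,
        append_fallback_rho=grid.append_fallback_rho,
        random_state=grid.seed,
    )
    est.fit(Z, y, covariates=covariates)
    return TuningResult(
        cv_table=est.cv_table_,
        best_gamma=est.best_gamma_,
        best_rho=est.best_rho_,
        best_score=est.best_score_,
        criterion=criterion,
        final_model=est.best_estimator_,
    )


def baseline_grid(gamma_values=DEFAULT_GAMMA_GRID, **kwargs) -> TuningGrid:
    """Tree-agnostic baseline: rho fixed at a very large value (1e4)."""
    return TuningGrid(
        rho_values=(FALLBACK_RHO,),
        gamma_values=tuple(gamma_values),
        append_fallback_rho=False,
        **kwargs,
    )


def pmse(y_obs, y_hat) -> float:
    """Predicted mean squared error."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y_obs) != len(y_hat):
        raise ValueError("length mismatch")
    return float(np.mean((y_obs - y_hat) ** 2))


def auc(y_obs, p_hat) -> float:
    """Rank-based area under the ROC curve (ties averaged)."""
    y_obs = np.asarray(y_obs).ravel()
    if len(np.unique(y_obs)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y_obs, np.asarray(p_hat, dtype=float).ravel()))


def r_squared(y_obs, y_hat) -> float:
    """Squared sample correlation between observed and predicted values.

    For a binary outcome pass the predicted probabilities as ``y_hat``.
    Zero variance in either vector yields 0 with a warning.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y_obs) != len(y_hat):
        raise ValueError("length mismatch")
    a = y_obs - y_obs.mean()
    b = y_hat - y_hat.mean()
    va, vb = float(a @ a), float(b @ b)
    if va <= 0 or vb <= 0:
        warnings.warn("zero variance; R^2 defined as 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return float((a @ b) ** 2 / (va * vb))
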