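"""Penalized quasi-likelihood (PQL) fit of the binary-outcome kernel GLMM.

The logistic mixed model ``logit E(y) = X beta + h``, with the aggregate
OTU effect ``h ~ N(0, sigma_b^2 K)``, is fitted by iterating weighted
working linear mixed models: at each outer step the current linear
predictor ``eta`` defines fitted probabilities ``mu``, IRLS weights
``w = mu (1 - mu)`` and the adjusted response
``y_work = eta + (y - mu) / w``; the working LMM
``y_work ~ N(X beta + h, sigma_b^2 K + sigma_e2 W^{-1})`` is refit and
``eta`` updated until it stabilizes.

The working-model dispersion ``sigma_e2`` is estimated by REML rather than
fixed at 1 (the classical quasi-likelihood scale); fix_dispersion=1.0
restores the textbook behaviour.  Prediction for new samples extrapolates
the working LMM at convergence and maps the predicted linear predictor
through the inverse logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .lmm import FittedModel, Prediction, fit_lmm, predict_lmm

WEIGHT_FLOOR = 1e-6
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 50


@dataclass
class PqlState:
    """Converged working-model state of the PQL iteration."""

    eta: np.ndarray = field(repr=False)
    working_y: np.ndarray = field(repr=False)
    working_w: np.ndarray = field(repr=False)
    iteration: int = 0
    converged: bool = False
    eta_step_history: list[float] = field(default_factory=list, repr=False)


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    fix_dispersion: float | None = None,
) -> tuple[FittedModel, PqlState]:
    """PQL fit; returns the converged working LMM plus the PQL state.

    Non-convergence is flagged (``state.converged is False``), not raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("binary outcome must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("outcome contains a single class")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)

    mu = (y + 0.5) / 2.0
    eta = logit(mu)
    model: FittedModel | None = None
    state = PqlState(eta=eta, working_y=eta, working_w=np.full(n, 0.25))
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), WEIGHT_FLOOR)
        y_work = eta + (y - mu) / w
        model = fit_lmm(y_work, X, K, obs_weights=w)
        if fix_dispersion is not None:
            model.sigma_e2_hat = float(fix_dispersion)
        eta_new = _working_linear_predictor(model)
        step = float(np.max(np.abs(eta_new - eta)))
        state.eta_step_history.append(step)
        eta = eta_new
        state.eta = eta
        state.working_y = y_work
        state.working_w = w
        state.iteration = it
        if step < tol:
            state.converged = True
            break
    return model, state


def _working_linear_predictor(model: FittedModel) -> np.ndarray:
    """BLUP-smoothed linear predictor of the working LMM on training data."""
    pred = predict_lmm(model, model.X_train, model.K_train)
    return pred.y_hat


def predict_glmm(
    model: FittedModel,
    state: PqlState,
    X_te: np.ndarray,
    K_te_tr: np.ndarray,
) -> np.ndarray:
    """Class probabilities for new samples via the converged working LMM."""
    pred: Prediction = predict_lmm(model, X_te, K_te_tr)
    return expit(pred.y_hat)
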