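"""REML estimation and conditional-mean prediction for the kernel LMM.

Model: ``y ~ N(X beta, sigma_b^2 K + sigma_e^2 I)`` where ``K`` is a sample
kernel (here the phylogeny-based kernel) and ``X`` a fixed-effect design
with a leading intercept column.  The restricted likelihood is profiled
down to the single ratio ``delta = sigma_e^2 / sigma_b^2`` after one
eigendecomposition of the projected kernel, in the spirit of the
efficient mixed-model association (EMMA) algorithm: a log-spaced grid over
``delta`` brackets the optimum and a bounded scalar minimization refines
it.  The boundary ``sigma_b^2 = 0`` (ordinary least squares) is always
considered as a candidate.

Prediction of new samples uses the conditional mean of the joint Gaussian,

    y_hat_te = X_te beta + Sigma_te,tr Sigma_tr^{-1} (y_tr - X_tr beta),

which is algebraically identical to pushing the BLUP of the per-OTU random
effects through the test abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize_scalar

DELTA_LOG10_RANGE = (-6.0, 6.0)
DELTA_GRID_POINTS = 61


class EstimationError(ValueError):
    pass


def build_design(n: int, covariates: np.ndarray | None = None) -> np.ndarray:
    """Fixed-effect design: all-ones intercept column plus covariates."""
    X = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate row count does not match samples")
        X = np.hstack([X, cov])
    return X


@dataclass
class FittedModel:
    """REML estimates plus the training-side pieces needed for prediction.

    ``obs_weights`` is ``None`` for an ordinary LMM; when set (by the PQL
    path) the residual covariance is ``sigma_e2 * diag(1/w)`` instead of
    ``sigma_e2 * I``.
    """

    beta_hat: np.ndarray
    sigma_b2_hat: float
    sigma_e2_hat: float
    reml_loglik: float
    delta: float
    boundary: bool
    y_train: np.ndarray = field(repr=False)
    X_train: np.ndarray = field(repr=False)
    K_train: np.ndarray = field(repr=False)
    obs_weights: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_train(self) -> int:
        return len(self.y_train)

    def sigma_train(self) -> np.ndarray:
        """Training covariance ``sigma_b2 K + sigma_e2 W^{-1}``."""
        n = self.n_train
        resid_var = self.sigma_e2_hat * (
            np.ones(n) if self.obs_weights is None else 1.0 / self.obs_weights
        )
        return self.sigma_b2_hat * self.K_train + np.diag(resid_var)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        arrays = {"beta_hat", "y_train", "X_train", "K_train"}
        kw = {}
        for k, v in d.items():
            if k in arrays or (k == "obs_weights" and v is not None):
                v = np.asarray(v, dtype=float)
            kw[k] = v
        return cls(**kw)


@dataclass
class Prediction:
    y_hat: np.ndarray
    variance: np.ndarray | None = None


def _validate_inputs(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = np.asarray(K, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X rows must match length of y")
    if K.shape != (n, n):
        raise ValueError("K must be n x n")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("fixed-effect design is rank deficient")
    if n < X.shape[1] + 2:
        raise EstimationError("need at least q + 2 samples")
    return y, X, K


def _projected_spectrum(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """Eigenpairs of S(K+I)S restricted to the complement of col(X).

    Returns ``lam`` (eigenvalues of SKS on that subspace, clipped at 0) and
    ``eta`` (rotated residual contrasts ``U^T y``).
    """
    n, q = X.shape
    Q, _ = np.linalg.qr(X)
    KQ = K @ Q
    SKS = K - Q @ (Q.T @ K) - KQ @ Q.T + Q @ (Q.T @ KQ) @ Q.T
    S = np.eye(n) - Q @ Q.T
    M = SKS + S  # = S(K+I)S since S is idempotent
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    keep = w > 0.5  # n-q eigenvalues >= 1 on col(S); q zeros on col(X)
    if keep.sum() != n - q:
        # fall back to taking the n-q largest
        order = np.argsort(w)[::-1][: n - q]
        keep = np.zeros(n, bool)
        keep[order] = True
    lam = np.maximum(w[keep] - 1.0, 0.0)
    U = V[:, keep]
    eta = U.T @ y
    return lam, eta


def _reml_loglik_profiled(delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    """Restricted log-likelihood profiled over beta and sigma_b2."""
    nq = len(lam)
    denom = lam + delta
    r = float(np.sum(eta2 / denom))
    return 0.5 * (
        nq * np.log(nq / (2 * np.pi))
        - nq
        - nq * np.log(r)
        - float(np.sum(np.log(denom)))
    )


def _ols_fit(y, X, K) -> FittedModel:
    n, q = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma_e2 = float(resid @ resid) / (n - q)
    nq = n - q
    ll = 0.5 * (nq * np.log(nq / (2 * np.pi)) - nq - nq * np.log(resid @ resid))
    return FittedModel(
        beta_hat=beta,
        sigma_b2_hat=0.0,
        sigma_e2_hat=sigma_e2,
        reml_loglik=ll,
        delta=np.inf,
        boundary=True,
        y_train=y,
        X_train=X,
        K_train=K,
    )


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    obs_weights: np.ndarray | None = None,
) -> FittedModel:
    """REML fit of ``y ~ N(X beta, sigma_b2 K + sigma_e2 W^{-1})``.

    With ``obs_weights`` given, the fit is carried out on the rescaled
    problem ``W^{1/2} y``; estimates are returned on the original scale.
    """
    from .kernel import check_psd

    y, X, K = _validate_inputs(y, X, K)
    K = check_psd(K)

    if obs_weights is not None:
        w = np.asarray(obs_weights, dtype=float).ravel()
        sw = np.sqrt(w)
        ys, Xs, Ks = y * sw, X * sw[:, None], K * sw[:, None] * sw[None, :]
    else:
        ys, Xs, Ks = y, X, K

    lam_max = float(np.linalg.eigvalsh(Ks)[-1]) if Ks.size else 0.0
    if lam_max <= 1e-12:
        model = _ols_fit(ys, Xs, Ks)
    else:
        lam, eta = _projected_spectrum(ys, Xs, Ks)
        eta2 = eta * eta
        lo, hi = DELTA_LOG10_RANGE
        grid = np.logspace(lo, hi, DELTA_GRID_POINTS)
        lls = np.array([_reml_loglik_profiled(d, lam, eta2) for d in grid])
        i = int(np.argmax(lls))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda t: -_reml_loglik_profiled(np.exp(t), lam, eta2),
            bounds=(np.log(a), np.log(b)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        delta = float(np.exp(res.x))
        ll = -float(res.fun)
        nq = len(lam)
        sigma_b2 = float(np.sum(eta2 / (lam + delta))) / nq
        sigma_e2 = delta * sigma_b2
        # OLS (sigma_b2 = 0) is the delta -> inf limit; prefer it when it
        # is at least as good, or when the optimum sits on the upper edge.
        ols = _ols_fit(ys, Xs, Ks)
        at_upper = i == len(grid) - 1
        if at_upper or ols.reml_loglik >= ll - 1e-10:
            model = ols
        else:
            Sigma = sigma_b2 * Ks + sigma_e2 * np.eye(len(ys))
            beta = _gls_beta(ys, Xs, Sigma)
            model = FittedModel(
                beta_hat=beta,
                sigma_b2_hat=sigma_b2,
                sigma_e2_hat=sigma_e2,
                reml_loglik=ll,
                delta=delta,
                boundary=i == 0,
                y_train=ys,
                X_train=Xs,
                K_train=Ks,
            )

    # re-express on the original (unweighted) scale
    model.y_train = y
    model.X_train = X
    model.K_train = K
    model.obs_weights = None if obs_weights is None else w
    return model


def _gls_beta(y, X, Sigma) -> np.ndarray:
    c, low = _chol_jitter(Sigma)
    Si_X = sla.cho_solve((c, low), X)
    Si_y = sla.cho_solve((c, low), y)
    return np.linalg.solve(X.T @ Si_X, X.T @ Si_y)


def _chol_jitter(Sigma: np.ndarray):
    """Cholesky with one retry after adding a trace-scaled jitter."""
    try:
        return sla.cho_factor(Sigma, lower=True)
    except np.linalg.LinAlgError:
        pass
    except sla.LinAlgError:
        pass
    jitter = 1e-8 * np.trace(Sigma) / Sigma.shape[0]
    warnings.warn(
        "training covariance not positive definite; adding diagonal jitter",
        RuntimeWarning,
        stacklevel=2,
    )
    try:
        return sla.cho_factor(Sigma + jitter * np.eye(Sigma.shape[0]), lower=True)
    except (np.linalg.LinAlgError, sla.LinAlgError) as exc:
        raise EstimationError("training covariance is singular") from exc


def predict_lmm(
    model: FittedModel,
    X_te: np.ndarray,
    K_te_tr: np.ndarray,
    K_te: np.ndarray | None = None,
    return_variance: bool = False,
) -> Prediction:
    """Conditional-mean prediction for new samples.

    ``K_te_tr`` is the (n_te x n_tr) cross kernel between test and training
    abundances.  With ``return_variance`` and ``K_te`` given, the diagonal
    of the conditional covariance is also returned.
    """
    X_te = np.atleast_2d(np.asarray(X_te, dtype=float))
    K_te_tr = np.atleast_2d(np.asarray(K_te_tr, dtype=float))
    if X_te.shape[1] != len(model.beta_hat):
        raise ValueError("test design width does not match fitted coefficients")
    if K_te_tr.shape != (X_te.shape[0], model.n_train):
        raise ValueError("cross-kernel shape does not match test/train sizes")

    mean_fixed = X_te @ model.beta_hat
    if model.sigma_b2_hat == 0.0 or not np.any(K_te_tr):
        y_hat = mean_fixed
        var = None
        if return_variance and K_te is not None:
            var = model.sigma_b2_hat * np.diag(np.atleast_2d(K_te)).copy()
        return Prediction(y_hat, var)

    Sigma_tr = model.sigma_train()
    c, low = _chol_jitter(Sigma_tr)
    resid = model.y_train - model.X_train @ model.beta_hat
    alpha = sla.cho_solve((c, low), resid)
    cross = model.sigma_b2_hat * K_te_tr
    y_hat = mean_fixed + cross @ alpha
    var = None
    if return_variance:
        if K_te is None:
            raise ValueError("K_te is required for predictive variance")
        Si_cross = sla.cho_solve((c, low), cross.T)
        var = (
            model.sigma_b2_hat * np.diag(np.atleast_2d(K_te))
            - np.einsum("ij,ji->i", cross, Si_cross)
        )
        var = np.maximum(var, 0.0)
    return Prediction(y_hat, var)
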