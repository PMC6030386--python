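"""scikit-learn style estimators for phylogenetic kernel mixed models.

``PhyloKernelRegressor`` fits the continuous-outcome LMM by REML;
``PhyloKernelClassifier`` fits the binary-outcome GLMM by PQL.  Both take
the feature matrix ``X`` as a (samples x OTUs) table of relative
abundances whose columns follow the tip order of the supplied phylogeny
(pandas DataFrames are reordered by OTU label automatically).  Extra
fixed-effect covariates are passed to ``fit``/``predict`` via the
``covariates`` keyword; an intercept is always included.

The CV variants (:class:`PhyloKernelRegressorCV`,
:class:`PhyloKernelClassifierCV`) grid-search the kernel tuning pair
``(gamma, rho)`` by k-fold cross-validation — predicted mean squared error
for regression, AUC for classification — then refit on all data at the
selected cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import lmm as _lmm
from . import pql as _pql
from .kernel import KernelSpec, correlation_matrix, kernel, power_transform
from .tree import AlignmentError, PhyloDistances

#: Evolutionary-rate grid: 0 plus powers of two from 2^-5 to 2^5.  A very
#: large value (1e4, effectively an identity correlation: the tree-agnostic
#: fallback) is appended by the CV estimators unless already present.
DEFAULT_RHO_GRID = tuple([0.0] + [2.0**k for k in range(-5, 6)])
DEFAULT_GAMMA_GRID = (0.0, 0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3, 1.5, 1.7, 1.9)
FALLBACK_RHO = 1e4


def _as_abundance_array(X, dist: PhyloDistances) -> np.ndarray:
    """Coerce/align a (samples x OTUs) table to the tip-label order."""
    if isinstance(X, pd.DataFrame):
        cols = [str(c) for c in X.columns]
        if set(cols) != set(dist.tip_labels):
            inter = len(set(cols) & set(dist.tip_labels))
            raise AlignmentError(
                f"abundance columns do not match tree tips "
                f"({inter}/{dist.n_tips} shared labels)"
            )
        X = X.loc[:, dist.tip_labels].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != dist.n_tips:
        raise AlignmentError(
            f"abundance matrix has {X.shape[1]} columns, tree has "
            f"{dist.n_tips} tips"
        )
    return X


class _PhyloKernelBase(BaseEstimator):
    def __init__(
        self,
        distances: PhyloDistances | None = None,
        rho: float = 1.0,
        gamma: float = 1.0,
        squared_distance: bool = True,
        rescale_distances: bool = False,
    ):
        self.distances = distances
        self.rho = rho
        self.gamma = gamma
        self.squared_distance = squared_distance
        self.rescale_distances = rescale_distances

    def _prepare(self, X):
        if self.distances is None:
            raise ValueError("a PhyloDistances instance is required")
        dist = (
            self.distances.rescaled() if self.rescale_distances else self.distances
        )
        Z = _as_abundance_array(X, dist)
        spec = KernelSpec(
            rho=self.rho, gamma=self.gamma, squared_distance=self.squared_distance
        )
        return dist, Z, spec

    def _cross_kernel(self, Z_te: np.ndarray) -> np.ndarray:
        F_te = power_transform(Z_te, self.spec_.gamma)
        return F_te @ self._CFt_

    def _fit_kernel(self, X):
        dist, Z, spec = self._prepare(X)
        corr = correlation_matrix(dist, spec)
        K = kernel(Z, Z, dist, spec, C=corr.C)
        self.dist_ = dist
        self.spec_ = spec
        self.pd_corrected_ = corr.pd_corrected
        self.Z_train_ = Z
        # C f(Z_tr)^T, cached so cross kernels are a single matmul
        self._CFt_ = corr.C @ power_transform(Z, spec.gamma).T
        self.n_features_in_ = Z.shape[1]
        return Z, K


class PhyloKernelRegressor(RegressorMixin, _PhyloKernelBase):
    """Continuous-outcome phylogenetic kernel mixed model (REML).

    Parameters
    ----------
    distances
        Patristic distances over the OTUs (tree tips).
    rho, gamma, squared_distance
        Kernel tuning state; see :mod:`phyloglmm.kernel`.
    rescale_distances
        Divide distances by their median off-diagonal before use.

    Attributes
    ----------
    beta_ : fixed-effect coefficients, intercept first.
    sigma_b2_, sigma_e2_ : variance components.
    reml_loglik_ : restricted log-likelihood at the optimum.
    """

    def fit(self, X, y, covariates=None):
        Z, K = self._fit_kernel(X)
        y = np.asarray(y, dtype=float).ravel()
        Xd = _lmm.build_design(len(y), covariates)
        self.model_ = _lmm.fit_lmm(y, Xd, K)
        self.beta_ = self.model_.beta_hat
        self.sigma_b2_ = self.model_.sigma_b2_hat
        self.sigma_e2_ = self.model_.sigma_e2_hat
        self.reml_loglik_ = self.model_.reml_loglik
        return self

    def predict(self, X, covariates=None, return_variance: bool = False):
        check_is_fitted(self, "model_")
        Z_te = _as_abundance_array(X, self.dist_)
        X_te = _lmm.build_design(Z_te.shape[0], covariates)
        K_te_tr = self._cross_kernel(Z_te)
        if return_variance:
            K_te = kernel(Z_te, Z_te, self.dist_, self.spec_)
            pred = _lmm.predict_lmm(
                self.model_, X_te, K_te_tr, K_te=K_te, return_variance=True
            )
            return pred.y_hat, pred.variance
        return _lmm.predict_lmm(self.model_, X_te, K_te_tr).y_hat


class PhyloKernelClassifier(ClassifierMixin, _PhyloKernelBase):
    """Binary-outcome phylogenetic kernel mixed model (PQL).

    Accepts any two-class label vector; internally codes the larger class
    label as 1.  ``predict_proba`` returns working-LMM extrapolated
    probabilities, ``predict`` thresholds at 1/2.
    """

    def __init__(
        self,
        distances: PhyloDistances | None = None,
        rho: float = 1.0,
        gamma: float = 1.0,
        squared_distance: bool = True,
        rescale_distances: bool = False,
        tol: float = _pql.DEFAULT_TOL,
        max_iter: int = _pql.DEFAULT_MAX_ITER,
        fix_dispersion: float | None = None,
    ):
        super().__init__(distances, rho, gamma, squared_distance, rescale_distances)
        self.tol = tol
        self.max_iter = max_iter
        self.fix_dispersion = fix_dispersion

    def fit(self, X, y, covariates=None):
        Z, K = self._fit_kernel(X)
        y = np.asarray(y).ravel()
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("classifier requires exactly two classes")
        y01 = (y == self.classes_[1]).astype(float)
        Xd = _lmm.build_design(len(y01), covariates)
        self.model_, self.pql_state_ = _pql.fit_glmm(
            y01,
            Xd,
            K,
            tol=self.tol,
            max_iter=self.max_iter,
            fix_dispersion=self.fix_dispersion,
        )
        self.converged_ = self.pql_state_.converged
        self.beta_ = self.model_.beta_hat
        self.sigma_b2_ = self.model_.sigma_b2_hat
        self.sigma_e2_ = self.model_.sigma_e2_hat
        return self

    def predict_proba(self, X, covariates=None):
        check_is_fitted(self, "model_")
        Z_te = _as_abundance_array(X, self.dist_)
        X_te = _lmm.build_design(Z_te.shape[0], covariates)
        K_te_tr = self._cross_kernel(Z_te)
        p1 = _pql.predict_glmm(self.model_, self.pql_state_, X_te, K_te_tr)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, covariates=None):
        p = self.predict_proba(X, covariates=covariates)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]


class _PhyloKernelCVBase(BaseEstimator):
    """Shared (gamma, rho) grid search by k-fold cross-validation."""

    _is_classifier = False

    def __init__(
        self,
        distances: PhyloDistances | None = None,
        rho_grid=None,
        gamma_grid=None,
        n_folds: int = 5,
        squared_distance: bool = True,
        rescale_distances: bool = False,
        append_fallback_rho: bool = True,
        random_state: int = 0,
    ):
        self.distances = distances
        self.rho_grid = rho_grid
        self.gamma_grid = gamma_grid
        self.n_folds = n_folds
        self.squared_distance = squared_distance
        self.rescale_distances = rescale_distances
        self.append_fallback_rho = append_fallback_rho
        self.random_state = random_state

    # -- hooks implemented by the two subclasses ------------------------
    def _make_estimator(self, rho, gamma):
        raise NotImplementedError

    def _fold_score(self, K_full, y, tr, te, covariates):
        raise NotImplementedError

    def _grids(self):
        rhos = list(self.rho_grid if self.rho_grid is not None else DEFAULT_RHO_GRID)
        gammas = list(
            self.gamma_grid if self.gamma_grid is not None else DEFAULT_GAMMA_GRID
        )
        if self.append_fallback_rho and FALLBACK_RHO not in rhos:
            rhos = rhos + [FALLBACK_RHO]
        if not rhos or not gammas:
            raise ValueError("tuning grids must be non-empty")
        if any(r < 0 for r in rhos) or any(g < 0 for g in gammas):
            raise ValueError("grid values must be >= 0")
        return rhos, gammas

    def _folds(self, y):
        if self._is_classifier:
            splitter = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.random_state
            )
            return list(splitter.split(np.zeros(len(y)), y))
        splitter = KFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        return list(splitter.split(np.zeros(len(y))))

    def fit(self, X, y, covariates=None):
        if self.distances is None:
            raise ValueError("a PhyloDistances instance is required")
        dist = (
            self.distances.rescaled() if self.rescale_distances else self.distances
        )
        Z = _as_abundance_array(X, dist)
        y = np.asarray(y).ravel()
        rhos, gammas = self._grids()
        folds = self._folds(y)

        maximize = self._is_classifier  # AUC up, PMSE down
        table = np.full((len(gammas), len(rhos)), np.nan)
        corr_cache: dict[float, np.ndarray] = {}
        for gi, gamma in enumerate(gammas):
            F = power_transform(Z, gamma)
            for ri, rho in enumerate(rhos):
                if rho not in corr_cache:
                    spec = KernelSpec(
                        rho=rho, gamma=1.0, squared_distance=self.squared_distance
                    )
                    corr_cache[rho] = correlation_matrix(dist, spec).C
                K_full = F @ corr_cache[rho] @ F.T
                K_full = 0.5 * (K_full + K_full.T)
                scores = [
                    self._fold_score(K_full, y, tr, te, covariates)
                    for tr, te in folds
                ]
                table[gi, ri] = float(np.mean(scores))

        best_gi, best_ri = 0, 0
        best = table[0, 0]
        for gi in range(len(gammas)):
            for ri in range(len(rhos)):
                v = table[gi, ri]
                if (maximize and v > best) or (not maximize and v < best):
                    best, best_gi, best_ri = v, gi, ri
        self.best_gamma_ = float(gammas[best_gi])
        self.best_rho_ = float(rhos[best_ri])
        self.best_score_ = float(best)
        self.cv_table_ = pd.DataFrame(
            table,
            index=pd.Index(gammas, name="gamma"),
            columns=pd.Index(rhos, name="rho"),
        )
        self.best_estimator_ = self._make_estimator(self.best_rho_, self.best_gamma_)
        self.best_estimator_.fit(Z, y, covariates=covariates)
        return self

    def predict(self, X, covariates=None):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(X, covariates=covariates)


class PhyloKernelRegressorCV(RegressorMixin, _PhyloKernelCVBase):
    """Regressor with (gamma, rho) tuned by k-fold CV on prediction MSE."""

    _is_classifier = False

    def _make_estimator(self, rho, gamma):
        return PhyloKernelRegressor(
            distances=self.distances,
            rho=rho,
            gamma=gamma,
            squared_distance=self.squared_distance,
            rescale_distances=self.rescale_distances,
        )

    def _fold_score(self, K_full, y, tr, te, covariates):
        cov = None if covariates is None else np.asarray(covariates)[tr]
        cov_te = None if covariates is None else np.asarray(covariates)[te]
        Xd = _lmm.build_design(len(tr), cov)
        model = _lmm.fit_lmm(y[tr].astype(float), Xd, K_full[np.ix_(tr, tr)])
        X_te = _lmm.build_design(len(te), cov_te)
        y_hat = _lmm.predict_lmm(model, X_te, K_full[np.ix_(te, tr)]).y_hat
        return float(np.mean((y[te] - y_hat) ** 2))


class PhyloKernelClassifierCV(ClassifierMixin, _PhyloKernelCVBase):
    """Classifier with (gamma, rho) tuned by stratified k-fold CV on AUC."""

    _is_classifier = True

    def _make_estimator(self, rho, gamma):
        return PhyloKernelClassifier(
            distances=self.distances,
            rho=rho,
            gamma=gamma,
            squared_distance=self.squared_distance,
            rescale_distances=self.rescale_distances,
        )

    def _fold_score(self, K_full, y, tr, te, covariates):
        cov = None if covariates is None else np.asarray(covariates)[tr]
        cov_te = None if covariates is None else np.asarray(covariates)[te]
        y01 = (y == np.unique(y)[1]).astype(float)
        Xd = _lmm.build_design(len(tr), cov)
        model, state = _pql.fit_glmm(y01[tr], Xd, K_full[np.ix_(tr, tr)])
        X_te = _lmm.build_design(len(te), cov_te)
        p = _pql.predict_glmm(model, state, X_te, K_full[np.ix_(te, tr)])
        return float(roc_auc_score(y01[te], p))

    def fit(self, X, y, covariates=None):
        y = np.asarray(y).ravel()
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("classifier requires exactly two classes")
        counts = np.bincount((y == self.classes_[1]).astype(int))
        if counts.min() < self.n_folds:
            raise ValueError(
                "too few samples in the minority class for stratified folds"
            )
        return super().fit(X, y, covariates=covariates)

    def predict_proba(self, X, covariates=None):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict_proba(X, covariates=covariates)
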