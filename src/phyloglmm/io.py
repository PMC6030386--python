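"""TSV / Newick / JSON glue shared by the CLI.

Count tables are taxa x samples TSVs whose first column holds OTU ids
matching the tree tip labels; covariate and outcome tables are
samples x fields.  Orientation is sanity-checked against the tree by
label intersection and reported — never silently transposed.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .lmm import FittedModel
from .tree import AlignmentError, PhyloDistances


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_counts(df: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index_label="otu_id")


def read_outcome(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] != 1:
        raise ValueError("outcome table must have exactly one value column")
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    return s


def write_outcome(s: pd.Series, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        s.rename("outcome").to_csv(fh, sep="\t", index_label="sample_id")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def align(
    counts: pd.DataFrame,
    dist: PhyloDistances,
    outcome: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
):
    """Align a taxa x samples table, a tree, and per-sample tables.

    Returns ``(Z, dist, y, cov, sample_ids)`` with ``Z`` samples x OTUs in
    tip order.  Raises :class:`AlignmentError` with diagnostics when
    labels do not line up (including a probable-transposition hint).
    """
    tips = set(dist.tip_labels)
    row_hits = len(tips & set(counts.index))
    if row_hits < len(counts.index) or row_hits < dist.n_tips:
        col_hits = len(tips & set(counts.columns))
        hint = (
            " (column labels match the tree tips better: the table looks "
            "transposed — expected taxa as rows)"
            if col_hits > row_hits
            else ""
        )
        missing = sorted(set(counts.index) - tips)[:5] + sorted(
            tips - set(counts.index)
        )[:5]
        raise AlignmentError(
            f"count-table rows and tree tips do not match "
            f"({row_hits}/{dist.n_tips} shared){hint}; offenders include "
            f"{missing}"
        )
    dist = dist.reorder(list(counts.index))
    samples = list(counts.columns)
    y = cov = None
    if outcome is not None:
        missing = [s for s in samples if s not in outcome.index]
        if missing:
            raise AlignmentError(
                f"outcome table is missing samples, e.g. {missing[:5]}"
            )
        y = outcome.loc[samples].to_numpy(dtype=float)
    if covariates is not None:
        missing = [s for s in samples if s not in covariates.index]
        if missing:
            raise AlignmentError(
                f"covariate table is missing samples, e.g. {missing[:5]}"
            )
        cov = covariates.loc[samples].to_numpy(dtype=float)
    Z = counts.T.to_numpy(dtype=float)
    return Z, dist, y, cov, samples


def provenance(seed: int | None = None, **params: Any) -> dict:
    return {"package": "phyloglmm", "version": __version__, "seed": seed, **params}


def save_estimator(path, est, meta: dict) -> None:
    """Serialize a fitted kernel-model estimator to one JSON document."""
    from .estimators import PhyloKernelClassifier

    doc = {
        "provenance": meta,
        "kind": "classifier" if isinstance(est, PhyloKernelClassifier) else "regressor",
        "params": {
            "rho": est.spec_.rho,
            "gamma": est.spec_.gamma,
            "squared_distance": est.spec_.squared_distance,
        },
        "tip_labels": est.dist_.tip_labels,
        "distances": est.dist_.D.tolist(),
        "Z_train": est.Z_train_.tolist(),
        "model": est.model_.to_dict(),
    }
    if doc["kind"] == "classifier":
        doc["classes"] = np.asarray(est.classes_).tolist()
        doc["converged"] = bool(est.converged_)
        doc["pql_state"] = {
            "eta": est.pql_state_.eta.tolist(),
            "working_y": est.pql_state_.working_y.tolist(),
            "working_w": est.pql_state_.working_w.tolist(),
            "iteration": est.pql_state_.iteration,
            "converged": est.pql_state_.converged,
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_estimator(path):
    """Rebuild a fitted estimator saved by :func:`save_estimator`."""
    from .estimators import PhyloKernelClassifier, PhyloKernelRegressor
    from .kernel import KernelSpec, correlation_matrix, power_transform
    from .pql import PqlState

    with open(path) as fh:
        doc = json.load(fh)
    dist = PhyloDistances(doc["tip_labels"], np.asarray(doc["distances"]))
    params = doc["params"]
    cls = PhyloKernelClassifier if doc["kind"] == "classifier" else PhyloKernelRegressor
    est = cls(distances=dist, **params)
    est.dist_ = dist
    est.spec_ = KernelSpec(**params)
    est.Z_train_ = np.asarray(doc["Z_train"], dtype=float)
    est.n_features_in_ = est.Z_train_.shape[1]
    corr = correlation_matrix(dist, est.spec_)
    est.pd_corrected_ = corr.pd_corrected
    est._CFt_ = corr.C @ power_transform(est.Z_train_, est.spec_.gamma).T
    est.model_ = FittedModel.from_dict(doc["model"])
    est.beta_ = est.model_.beta_hat
    est.sigma_b2_ = est.model_.sigma_b2_hat
    est.sigma_e2_ = est.model_.sigma_e2_hat
    if doc["kind"] == "classifier":
        est.classes_ = np.asarray(doc["classes"])
        est.converged_ = doc["converged"]
        st = doc["pql_state"]
        est.pql_state_ = PqlState(
            eta=np.asarray(st["eta"]),
            working_y=np.asarray(st["working_y"]),
            working_w=np.asarray(st["working_w"]),
            iteration=st["iteration"],
            converged=st["converged"],
        )
    else:
        est.reml_loglik_ = est.model_.reml_loglik
    return est, doc.get("provenance", {})
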