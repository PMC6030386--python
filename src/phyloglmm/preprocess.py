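"""Preprocessing pipeline for raw OTU count tables.

Fixed stage order: outlier-sample filter (Bray-Curtis based) -> OTU
filters (prevalence, median nonzero count) -> GMPR size-factor
normalization -> per-taxon 97%-quantile winsorization -> optional
square-root transform.  Tables are pandas DataFrames, taxa as rows and
samples as columns (the common OTU-table orientation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class PreprocessConfig:
    outlier_threshold: float = 2.0
    prevalence_min: float = 0.10
    median_nonzero_min: float = 10.0
    winsor_quantile: float = 0.97
    sqrt_transform: bool = True
    normalization: str = "gmpr"

    def __post_init__(self) -> None:
        if self.outlier_threshold <= 0 or self.median_nonzero_min <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.winsor_quantile < 1):
            raise ValueError("winsor quantile must be in (0, 1)")


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts.astype(float)
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    return pd.DataFrame(counts)


def outlier_filter(
    counts, threshold: float = 2.0
) -> tuple[list, pd.Series]:
    """Outlier index per sample; keep samples with ``o_j <= threshold``.

    ``o_j = m_j / median_k(m_k)`` where ``m_j`` is the median Bray-Curtis
    distance (computed on proportions) from sample ``j`` to all others.
    If all samples are identical the index is undefined and treated as 1.
    """
    df = _as_frame(counts)
    n = df.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    props = df.to_numpy().T
    totals = props.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("every sample needs a positive total count")
    props = props / totals
    dmat = squareform(pdist(props, metric="braycurtis"))
    med_j = np.array(
        [np.median(np.delete(dmat[j], j)) for j in range(n)]
    )
    med_all = float(np.median(med_j))
    if med_all == 0.0:
        warnings.warn(
            "all pairwise distances are zero; outlier index undefined, "
            "keeping every sample",
            RuntimeWarning,
            stacklevel=2,
        )
        o = np.ones(n)
    else:
        o = med_j / med_all
    o = pd.Series(o, index=df.columns, name="outlier_index")
    kept = [c for c, v in zip(df.columns, o) if v <= threshold]
    return kept, o


def otu_filter(
    counts, prevalence_min: float = 0.10, median_nonzero_min: float = 10.0
) -> tuple[list, pd.DataFrame]:
    """Keep OTUs passing both the prevalence and median-nonzero filters.

    Prevalence is the fraction of samples with a positive count; the
    median is taken over the nonzero counts only.  Also returns a
    per-rule report of the dropped OTU counts.
    """
    df = _as_frame(counts)
    mat = df.to_numpy()
    prevalence = (mat > 0).mean(axis=1)
    med_nonzero = np.array(
        [np.median(row[row > 0]) if (row > 0).any() else 0.0 for row in mat]
    )
    pass_prev = prevalence >= prevalence_min
    pass_med = med_nonzero >= median_nonzero_min
    keep = pass_prev & pass_med
    report = pd.DataFrame(
        {
            "prevalence": prevalence,
            "median_nonzero": med_nonzero,
            "kept": keep,
        },
        index=df.index,
    )
    kept = list(df.index[keep])
    if not kept:
        raise ValueError(
            f"no OTU passes the filters (prevalence dropped "
            f"{int((~pass_prev).sum())}, median-count dropped "
            f"{int((~pass_med).sum())})"
        )
    return kept, report


def size_factor_normalize(counts) -> tuple[pd.DataFrame, pd.Series]:
    """GMPR normalization: divide each sample by its size factor ``s_j``.

    ``s_j`` is the geometric mean over other samples ``k`` of the median
    count ratio ``c_ij / c_ik`` over taxa present in both samples; the
    factors are rescaled to geometric mean 1.  Designed for zero-inflated
    counts: only co-detected taxa enter each pairwise ratio.
    """
    df = _as_frame(counts)
    mat = df.to_numpy()
    p, n = mat.shape
    log_s = np.zeros(n)
    for j in range(n):
        cj = mat[:, j]
        med_ratios = [1.0]  # trivial self-ratio; keeps pure scalings exact
        shared_with_other = False
        for k in range(n):
            if k == j:
                continue
            ck = mat[:, k]
            both = (cj > 0) & (ck > 0)
            if both.any():
                shared_with_other = True
                med_ratios.append(np.median(cj[both] / ck[both]))
        if not shared_with_other:
            raise ValueError(
                f"sample {df.columns[j]!r} shares no detected taxon with "
                "any other sample"
            )
        log_s[j] = np.mean(np.log(med_ratios))
    log_s -= log_s.mean()  # geometric mean of s_j == 1
    s = pd.Series(np.exp(log_s), index=df.columns, name="size_factor")
    return df / s, s


def winsorize(values, q: float = 0.97) -> pd.DataFrame:
    """Cap each taxon's values at its empirical ``q``-quantile.

    Quantiles use the lower order-statistic (inverted empirical CDF)
    convention: the cap is always an observed value, which makes the
    operation exactly idempotent — the capped table has the same quantile,
    so a second pass changes nothing.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    df = _as_frame(values)
    caps = df.quantile(q, axis=1, interpolation="lower")
    return df.clip(upper=caps, axis=0)


@dataclass
class PipelineResult:
    table: pd.DataFrame = field(repr=False)
    removed_samples: list = field(default_factory=list)
    removed_otus: list = field(default_factory=list)
    outlier_index: pd.Series | None = None
    size_factors: pd.Series | None = None
    stage_dims: list = field(default_factory=list)


def run_pipeline(counts, config: PreprocessConfig | None = None) -> PipelineResult:
    """Full preprocessing pass over a (taxa x samples) count table."""
    config = config or PreprocessConfig()
    df = _as_frame(counts)
    dims = [("input", df.shape)]

    kept_samples, o = outlier_filter(df, threshold=config.outlier_threshold)
    removed_samples = [c for c in df.columns if c not in set(kept_samples)]
    df = df[kept_samples]
    dims.append(("sample_filter", df.shape))

    kept_otus, _ = otu_filter(
        df,
        prevalence_min=config.prevalence_min,
        median_nonzero_min=config.median_nonzero_min,
    )
    removed_otus = [r for r in df.index if r not in set(kept_otus)]
    df = df.loc[kept_otus]
    dims.append(("otu_filter", df.shape))

    df, s = size_factor_normalize(df)
    dims.append(("normalize", df.shape))

    df = winsorize(df, q=config.winsor_quantile)
    dims.append(("winsorize", df.shape))

    if config.sqrt_transform:
        df = np.sqrt(df)
        dims.append(("sqrt", df.shape))

    return PipelineResult(
        table=df,
        removed_samples=removed_samples,
        removed_otus=removed_otus,
        outlier_index=o,
        size_factors=s,
        stage_dims=dims,
    )
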