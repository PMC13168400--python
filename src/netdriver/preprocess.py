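"""Expression preprocessing: depth normalization, expression filtering,
batch adjustment and PCA quality control.

The processing chain mirrors a standard bulk RNA-seq workflow for a
two-cell-line knockdown experiment:

1. depth-normalize and log2-transform raw counts,
2. drop features that are essentially unexpressed (at or below the 5th
   percentile of their sample in >= 90% of samples),
3. remove cell-line batch effects with parametric empirical-Bayes
   location/scale adjustment (ComBat) while preserving the
   knockdown-vs-control contrast,
4. PCA scores for visual QC of batch removal.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DegenerateDepthError(ValueError):
    """A sample column sums to zero, so its depth is undefined."""


class ConfoundingError(ValueError):
    """Batch labels coincide 1:1 with condition labels."""


def normalize_log2(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth-normalize counts and log2 transform.

    Each count is incremented by one and multiplied by the sample's
    scaling factor — the mean sequencing depth across samples divided by
    the sample's own depth (depth = column sum of raw counts):

        value(g, s) = log2((count(g, s) + 1) * mean_depth / depth(s))

    Returns
    -------
    (expression matrix, normalization factors) — the factor table has
    one row per sample with columns ``depth`` and ``factor``.
    """
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    depths = counts.sum(axis=0).astype(float)
    if (depths <= 0).any():
        bad = depths.index[depths <= 0][0]
        raise DegenerateDepthError(f"sample {bad!r} has zero depth")
    factors = depths.mean() / depths
    expr = np.log2((counts.astype(float) + 1.0) * factors)
    norm = pd.DataFrame({"depth": depths, "factor": factors})
    norm.index.name = "sample_id"
    return expr, norm


def filter_low_expression(
    expr: pd.DataFrame,
    pct: float = 5.0,
    frac: float = 0.90,
    thresholds: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop features unexpressed in most samples.

    A feature is removed iff its value is at or below the per-sample
    `pct`-th percentile (linear interpolation across that sample's
    features) in at least ``ceil(frac * n_samples)`` samples.

    Parameters
    ----------
    thresholds
        Precomputed per-sample cutoffs; passing the thresholds returned
        by a previous call makes the operation idempotent.

    Returns
    -------
    (filtered matrix, per-sample thresholds used).
    """
    if expr.empty:
        raise ValueError("empty expression matrix")
    if not 0.0 < pct < 100.0:
        raise ValueError("pct must lie strictly between 0 and 100")
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    if thresholds is None:
        thresholds = pd.Series(
            np.percentile(expr.to_numpy(float), pct, axis=0),
            index=expr.columns,
        )
    n_needed = math.ceil(frac * expr.shape[1])
    below = (expr.le(thresholds, axis=1)).sum(axis=1)
    keep = below < n_needed
    logger.info("filter_low_expression: removed %d of %d features "
                "(<= p%g in >= %d of %d samples)",
                int((~keep).sum()), len(expr), pct, n_needed, expr.shape[1])
    return expr.loc[keep], thresholds


def _check_batches(meta: pd.DataFrame, batch_col: str, condition_col: str) -> None:
    batches = meta[batch_col].astype(str)
    conds = meta[condition_col].astype(str)
    sizes = batches.value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2][0]
        raise ValueError(f"batch {small!r} has fewer than 2 samples")
    per_batch = conds.groupby(batches).nunique()
    if conds.nunique() > 1 and (per_batch == 1).all():
        raise ConfoundingError("every batch maps to a single condition; "
                               "batch and condition are confounded")
    if (per_batch == 1).any():
        logger.warning("batch %s contains a single condition; adjustment "
                       "may absorb part of the condition effect",
                       per_batch.index[per_batch == 1].tolist())


def batch_adjust(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    batch_col: str = "cell_line",
    condition_col: str = "condition",
    method: str = "eb",
) -> pd.DataFrame:
    """Remove batch effects while preserving the condition contrast.

    ``method="eb"`` is parametric ComBat (empirical-Bayes location/scale
    adjustment with the condition kept in the standardization design).
    ``method="center"`` is a simpler fallback: per-feature, per-batch
    mean-centering of the residuals left after removing condition means
    (location-only, no shrinkage, exact in the balanced case).

    A single-batch input is returned unchanged.
    """
    meta = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    meta = meta[~meta.index.duplicated()]
    missing = [s for s in expr.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    meta = meta.loc[list(expr.columns)]
    if meta[batch_col].nunique() == 1:
        return expr.copy()
    _check_batches(meta, batch_col, condition_col)

    if method == "center":
        cond = meta[condition_col].astype(str)
        batch = meta[batch_col].astype(str)
        cond_means = expr.T.groupby(cond.values).mean().T
        resid = expr - cond_means.reindex(columns=cond.values).set_axis(expr.columns, axis=1)
        batch_off = resid.T.groupby(batch.values).mean().T
        return expr - batch_off.reindex(columns=batch.values).set_axis(expr.columns, axis=1)

    if method != "eb":
        raise ValueError(f"unknown batch adjustment method {method!r}")

    import anndata as ad
    import scanpy as sc

    obs = pd.DataFrame(index=pd.Index([str(c) for c in expr.columns]))
    obs["batch"] = meta[batch_col].astype(str).to_numpy()
    # numeric encoding: scanpy's design builder produces a singular
    # matrix when a *categorical* covariate duplicates the batch block
    obs["cond01"] = (meta[condition_col].astype(str) == "knockdown").to_numpy(float)
    adata = ad.AnnData(X=expr.T.to_numpy(float), obs=obs)
    sc.pp.combat(adata, key="batch", covariates=["cond01"])
    return pd.DataFrame(adata.X.T, index=expr.index.copy(), columns=expr.columns.copy())


def pca_scores(expr: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the leading principal components.

    Features are centered; components are ordered by non-increasing
    explained variance, which is stored in ``result.attrs``.
    """
    from sklearn.decomposition import PCA

    n_max = min(expr.shape)
    if not 1 <= n_components <= n_max:
        raise ValueError(f"n_components must lie in [1, {n_max}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(expr.T.to_numpy(float))
    out = pd.DataFrame(
        scores,
        index=pd.Index(expr.columns, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    out.attrs["explained_variance"] = pca.explained_variance_.tolist()
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return out
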