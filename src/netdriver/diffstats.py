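"""Empirical-Bayes moderated differential testing.

Differential expression (DE) and differential activity (DA) both use
the same machinery: a per-feature ordinary least-squares fit of the
(expression or activity) profile on the experimental condition,
followed by empirical-Bayes shrinkage of the residual variances toward
a common prior (the moderated t of Smyth 2004).  For feature *g* with
residual variance ``s_g^2`` on ``d`` degrees of freedom, the posterior
variance is

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and ``t_mod = beta_g / (s~_g * sqrt(v))`` is referred to a t
distribution with ``d0 + d`` degrees of freedom (``v`` is the contrast
variance factor from the design).  The prior df ``d0`` and prior
variance ``s0^2`` are estimated by moment-matching the scaled-F
distribution of the sample variances on the log scale (digamma /
trigamma matching).  ``d0 = 0`` recovers the classical per-feature t.

Reported alongside t are a two-sided p-value, its signed normal-quantile
z-score, and Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "knockdown")


@dataclass(frozen=True)
class EBParams:
    """Variance-shrinkage hyperparameters: prior df and prior variance."""

    prior_df: float
    prior_var: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:  # trigamma(x) ~ 1/x^2 for tiny x
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * x:
            x = x_new
            break
        x = x_new
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> EBParams:
    """Moment-match (d0, s0^2) from observed residual variances.

    Uses the log-variance representation: ``log s^2`` is distributed as
    ``log s0^2 + log F(d, d0)`` whose mean and variance involve digamma
    and trigamma functions of d/2 and d0/2.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise FloatingPointError("too few positive variances to fit a prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    if e_var < 1e-12:
        # degenerate input: zero spread means the common variance is known
        return EBParams(prior_df=np.inf, prior_var=float(np.exp(z.mean())))
    resid_var = e_var - float(special.polygamma(1, df / 2.0))
    if resid_var > 0:
        d0 = 2.0 * _trigamma_inverse(resid_var)
        s0 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0 = np.exp(e_mean)
    return EBParams(prior_df=float(d0), prior_var=float(s0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_moderated(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    condition_col: str = "condition",
    batch_col: str | None = None,
    prior_df: float | str = "estimate",
) -> pd.DataFrame:
    """Moderated knockdown-vs-control contrast, one row per feature.

    Parameters
    ----------
    matrix
        features x samples matrix (log2 expression, or activity scores).
    samples
        Per-sample metadata covering every column of `matrix`; the
        condition column must contain ``control`` / ``knockdown``.
    batch_col
        Optional column added to the design as a covariate (alternative
        to adjusting the matrix beforehand).
    prior_df
        ``"estimate"`` (default) fits d0 empirically; a number forces
        it (0 = classical t, ``inf`` = full shrinkage to the prior).

    Returns
    -------
    DataFrame indexed by feature with columns ``effect`` (knockdown -
    control coefficient), ``t_mod``, ``z``, ``p``, ``adj_p``.  The
    fitted :class:`EBParams` are stored in ``result.attrs["eb"]``.
    """
    meta = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    meta = meta[~meta.index.duplicated()]
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    meta = meta.loc[list(matrix.columns)]
    cond = meta[condition_col].astype(str)
    bad = set(cond) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    n_kd = int((cond == "knockdown").sum())
    n_ct = int((cond == "control").sum())
    if n_kd < 2 or n_ct < 2:
        raise ValueError("need at least 2 samples per condition")

    cols = [np.ones(len(cond)), (cond == "knockdown").to_numpy(float)]
    if batch_col is not None:
        batches = pd.get_dummies(meta[batch_col].astype(str), drop_first=True)
        cols.extend(batches[c].to_numpy(float) for c in batches.columns)
    X = np.column_stack(cols)
    n, p_params = X.shape
    df_resid = n - np.linalg.matrix_rank(X)
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")

    Y = matrix.to_numpy(float)
    xtx_inv = np.linalg.pinv(X.T @ X)
    H = xtx_inv @ X.T                     # p x n
    B = Y @ H.T                           # features x p
    resid = Y - B @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid
    v = float(xtx_inv[1, 1])              # contrast variance factor
    effect = B[:, 1]

    if prior_df == "estimate":
        try:
            eb = estimate_prior(s2, df_resid)
        except FloatingPointError:
            warnings.warn("prior df estimation failed; falling back to the "
                          "classical t (d0 = 0)", stacklevel=2)
            eb = EBParams(prior_df=0.0, prior_var=float(np.median(s2)))
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValueError("prior_df must be >= 0")
        if 0 < d0 < np.inf:
            s0 = estimate_prior(s2, df_resid).prior_var
        else:
            # unbiased log-scale location of the variance distribution
            pos = s2[s2 > 0]
            e_mean = float(np.log(pos).mean()) if pos.size else 0.0
            s0 = float(np.exp(e_mean - special.digamma(df_resid / 2.0)
                              + np.log(df_resid / 2.0)))
        eb = EBParams(prior_df=d0, prior_var=s0)

    if np.isinf(eb.prior_df):
        s2_post = np.full_like(s2, eb.prior_var)
        df_total = np.inf
    elif eb.prior_df == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (eb.prior_df * eb.prior_var + df_resid * s2) / (eb.prior_df + df_resid)
        df_total = eb.prior_df + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = effect / np.sqrt(s2_post * v)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 1e-300, 1.0)
    z = np.sign(t_mod) * stats.norm.isf(p / 2.0)
    out = pd.DataFrame(
        {"effect": effect, "t_mod": t_mod, "z": z, "p": p, "adj_p": bh_adjust(p)},
        index=matrix.index.copy(),
    )
    out.attrs["eb"] = eb
    out.attrs["df_resid"] = float(df_resid)
    return out


def call_de(table: pd.DataFrame, alpha: float = 0.05, lfc: float = 1.0) -> pd.DataFrame:
    """Differential-expression calls: adj_p <= alpha AND |log2FC| >= lfc.

    Both thresholds are inclusive.
    """
    out = table.copy()
    out["significant"] = (out["adj_p"] <= alpha) & (out["effect"].abs() >= lfc)
    return out


def call_da(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Differential-activity calls: adj_p <= alpha (no effect-size cut)."""
    out = table.copy()
    out["significant"] = out["adj_p"] <= alpha
    return out
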