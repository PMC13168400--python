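"""Regulatory-network containers and edge scoring.

A :class:`RegulatoryNetwork` is a validated edge list with one row per
(source, target) interaction.  Sources ("drivers") are transcription
factors (``TF``), signalling proteins (``SIG``) or miRNAs (``miRNA``);
the set of targets of one source is its *regulon*.  Edges carry an
optional regulatory sign, a Spearman correlation ``rho`` computed over
condition-group mean profiles, and a mutual-information weight ``mi``.

The scoring convention follows the unpaired-assay design of a two cell
line x two condition knockdown experiment: expression profiles are
averaged within the four (cell line, condition) groups and edge
correlations are computed across those four group means, so mRNA and
miRNA samples never need to be paired one-to-one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

SOURCE_CLASSES = ("TF", "SIG", "miRNA")

#: canonical edge-table columns
EDGE_COLUMNS = ("source", "target", "source_class", "sign", "rho", "mi")


class NetworkError(ValueError):
    """Malformed network structure (self-edges, duplicates, bad classes)."""


@dataclass
class RegulatoryNetwork:
    """Signed, weighted source->target edge list with per-source regulons.

    Parameters
    ----------
    edges
        DataFrame with columns ``source``, ``target``, ``source_class``
        and optionally ``sign`` (-1, +1, or 0 for unknown), ``rho`` and
        ``mi`` (NaN when unset).
    """

    edges: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.edges.copy()
        missing = {"source", "target", "source_class"} - set(df.columns)
        if missing:
            raise NetworkError(f"edge table lacks columns: {sorted(missing)}")
        for col, default in (("sign", 0), ("rho", np.nan), ("mi", np.nan)):
            if col not in df.columns:
                df[col] = default
        df = df.loc[:, list(EDGE_COLUMNS)].reset_index(drop=True)
        df["sign"] = df["sign"].fillna(0).astype(int)
        df["rho"] = df["rho"].astype(float)
        df["mi"] = df["mi"].astype(float)

        bad_class = set(df["source_class"]) - set(SOURCE_CLASSES)
        if bad_class:
            raise NetworkError(f"unknown source classes: {sorted(bad_class)}")
        if not df["sign"].isin((-1, 0, 1)).all():
            raise NetworkError("edge signs must be -1, +1 or 0 (unknown)")
        if (df["source"] == df["target"]).any():
            bad = df.loc[df["source"] == df["target"], "source"].iloc[0]
            raise NetworkError(f"self-edge on {bad!r}")
        dup = df.duplicated(subset=["source", "target"])
        if dup.any():
            pair = df.loc[dup, ["source", "target"]].iloc[0].tolist()
            raise NetworkError(f"duplicate edge {tuple(pair)}")
        self.edges = df

    # -- basic accessors -------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def drivers(self) -> list[str]:
        """Source ids, in first-appearance order."""
        return list(dict.fromkeys(self.edges["source"]))

    def nodes(self) -> set[str]:
        """All gene ids appearing as a source or a target."""
        return set(self.edges["source"]) | set(self.edges["target"])

    def driver_class(self) -> pd.Series:
        """Map source id -> source class."""
        return self.edges.drop_duplicates("source").set_index("source")[
            "source_class"
        ]

    def regulons(self) -> dict[str, pd.DataFrame]:
        """Per-source regulon: edge rows grouped by source."""
        return {src: grp for src, grp in self.edges.groupby("source", sort=False)}

    def regulon_sizes(self) -> pd.Series:
        return self.edges.groupby("source", sort=False).size()


# ---------------------------------------------------------------------------
# group-mean profiles
# ---------------------------------------------------------------------------

class DesignError(ValueError):
    """Sample design problem (empty group, unassigned sample)."""


def group_means(expr: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Average expression within each (cell line, condition) group.

    Parameters
    ----------
    expr
        features x samples expression matrix.
    samples
        per-sample metadata with columns ``cell_line`` and ``condition``,
        indexed by (or containing a column of) sample ids covering every
        column of `expr`.

    Returns
    -------
    features x groups matrix; group ids are ``"<cell_line>:<condition>"``.
    """
    meta = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    meta = meta[~meta.index.duplicated()]
    missing = [s for s in expr.columns if s not in meta.index]
    if missing:
        raise DesignError(f"samples without metadata: {missing[:5]}")
    meta = meta.loc[list(expr.columns)]
    key = meta["cell_line"].astype(str) + ":" + meta["condition"].astype(str)
    # every cell line must appear under every condition
    counts = pd.crosstab(meta["cell_line"], meta["condition"])
    if (counts == 0).any().any():
        raise DesignError("empty (cell line, condition) group")
    out = expr.T.groupby(key.values).mean().T
    out.index.name = expr.index.name
    return out


# ---------------------------------------------------------------------------
# Spearman scoring
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson correlation of average-ranked values.

    Returns NaN for constant input (the edge is then treated as
    unscored, and removed by miRNA-edge pruning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0.0:  # constant vector: correlation undefined
        return float("nan")
    return float((rx * ry).sum() / denom)


def _rank_rows(values: np.ndarray) -> np.ndarray:
    ranks = rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    return ranks


def score_edges(network: RegulatoryNetwork, profile: pd.DataFrame) -> RegulatoryNetwork:
    """Attach a Spearman ``rho`` to every edge, over group-mean profiles.

    Edges with an endpoint absent from `profile` are dropped (the count
    is logged).  Constant endpoints yield ``rho = NaN`` (unscored).
    """
    edges = network.edges
    present = edges["source"].isin(profile.index) & edges["target"].isin(profile.index)
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.info("score_edges: dropped %d edges with endpoints missing "
                    "from the profile", n_dropped)
    edges = edges.loc[present].reset_index(drop=True)

    ranks = _rank_rows(profile.to_numpy(float))
    norms = np.sqrt((ranks**2).sum(axis=1))
    pos = pd.Series(np.arange(len(profile)), index=profile.index)
    si = pos[edges["source"]].to_numpy()
    ti = pos[edges["target"]].to_numpy()
    denom = norms[si] * norms[ti]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0,
                       (ranks[si] * ranks[ti]).sum(axis=1) / np.where(denom > 0, denom, 1.0),
                       np.nan)
    edges = edges.assign(rho=rho)
    return RegulatoryNetwork(edges)


def prune_mirna_edges(network: RegulatoryNetwork) -> RegulatoryNetwork:
    """Remove miRNA-source edges whose correlation is not negative.

    miRNAs repress their targets, so only anti-correlated miRNA->target
    interactions are biologically plausible; edges with ``rho >= 0`` (or
    unscored, NaN) are removed.  TF/SIG edges are untouched.  Sources
    whose regulons become empty simply no longer appear.
    """
    edges = network.edges
    is_mirna = edges["source_class"] == "miRNA"
    keep = ~is_mirna | (edges["rho"] < 0)
    n_removed = int((~keep).sum())
    logger.info("prune_mirna_edges: removed %d of %d miRNA edges "
                "(non-negative or unscored rho); %d edges remain",
                n_removed, int(is_mirna.sum()), int(keep.sum()))
    return RegulatoryNetwork(edges.loc[keep].reset_index(drop=True))


def resolve_signs(network: RegulatoryNetwork) -> RegulatoryNetwork:
    """Fix the regulatory sign used by activity scoring.

    miRNA edges are repressive by definition (sign -1).  TF/SIG edges
    with an unknown sign take the sign of their correlation; edges whose
    sign cannot be resolved (rho zero or unscored) are dropped with a
    logged count.
    """
    edges = network.edges.copy()
    is_mirna = edges["source_class"] == "miRNA"
    edges.loc[is_mirna, "sign"] = -1
    unknown = (~is_mirna) & (edges["sign"] == 0)
    resolved = np.sign(edges.loc[unknown, "rho"].fillna(0.0)).astype(int)
    edges.loc[unknown, "sign"] = resolved
    bad = edges["sign"] == 0
    if bad.any():
        logger.info("resolve_signs: dropped %d edges with unresolvable sign",
                    int(bad.sum()))
        edges = edges.loc[~bad]
    return RegulatoryNetwork(edges.reset_index(drop=True))
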