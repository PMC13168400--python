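"""Readers and writers for the pipeline's tabular artifacts.

All formats are plain UTF-8 TSV (``#`` comment lines allowed) plus GMT
for gene sets.  Readers validate rather than coerce: malformed input
raises :class:`FormatError` with the offending value.  Every
writer/reader pair round-trips valid data exactly.

Conventions
-----------
* count / expression matrices: first column ``feature_id``, remaining
  columns one per sample;
* sample tables: columns ``sample_id``, ``cell_line``, ``condition``
  (``control`` | ``knockdown``), ``replicate``, ``assay`` (``mRNA`` |
  ``miRNA``);
* network edge lists: columns ``source``, ``target``, ``source_class``
  (``TF`` | ``SIG`` | ``miRNA``) and optional ``sign``, ``rho``, ``mi``;
* gene identifiers are used as given; an optional two-column mapping
  TSV (old id -> new id) can be applied before duplicate aggregation —
  no online lookups.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .network import EDGE_COLUMNS, RegulatoryNetwork

logger = logging.getLogger(__name__)

VALID_CONDITIONS = ("control", "knockdown")
VALID_ASSAYS = ("mRNA", "miRNA")


class FormatError(ValueError):
    """Malformed tabular input."""


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    if df.columns.duplicated().any() or any("." in c and c.rsplit(".", 1)[-1].isdigit()
                                            for c in df.columns):
        # pandas renames duplicate header fields; detect the originals
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    header = line.rstrip("\n").split("\t")
                    break
        if len(set(header)) != len(header):
            raise FormatError(f"{path}: duplicate column ids in header")
    return df


def read_id_mapping(path) -> dict[str, str]:
    """Two-column TSV mapping old feature ids to new ones."""
    df = _read_tsv(path)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: id mapping must have exactly 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_counts(path, aggregate_duplicates: bool = False,
                id_mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a genes x samples count matrix.

    Values must be non-negative integers.  With `aggregate_duplicates`,
    rows sharing a feature id (e.g. after symbol mapping) are summed
    element-wise; otherwise duplicates raise.  `id_mapping` renames
    features before aggregation.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a feature column plus >= 1 sample")
    features = df.iloc[:, 0]
    body = df.iloc[:, 1:]
    values = body.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        col = values.columns[values.isna().any()][0]
        bad = body.loc[values[col].isna(), col].iloc[0]
        raise FormatError(f"{path}: non-numeric entry {bad!r} in column {col!r}")
    arr = values.to_numpy()
    if (arr < 0).any():
        raise FormatError(f"{path}: negative count")
    if np.any(arr != np.floor(arr)):
        raise FormatError(f"{path}: non-integer count")
    counts = pd.DataFrame(arr.astype(np.int64), columns=values.columns)
    if id_mapping:
        features = features.map(lambda f: id_mapping.get(f, f))
    counts.index = pd.Index(features, name="feature_id")
    if counts.index.duplicated().any():
        if not aggregate_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"{path}: duplicate feature id {dup!r} "
                              "(pass aggregate_duplicates to sum them)")
        n_before = len(counts)
        counts = counts.groupby(level=0, sort=False).sum()
        logger.info("read_counts: aggregated %d duplicate rows into %d features",
                    n_before - len(counts), len(counts))
    return counts


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a features x samples matrix (counts or expression)."""
    out = matrix.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    """Read a features x samples real-valued expression matrix."""
    df = _read_tsv(path)
    features = df.iloc[:, 0]
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise FormatError(f"{path}: non-numeric expression entry")
    values.index = pd.Index(features, name="feature_id")
    if values.index.duplicated().any():
        raise FormatError(f"{path}: duplicate feature id")
    return values.astype(float)


def read_sample_table(path) -> pd.DataFrame:
    """Read and validate a per-sample design table."""
    df = _read_tsv(path)
    required = {"sample_id", "cell_line", "condition", "replicate", "assay"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample table lacks columns {sorted(missing)}")
    bad_cond = set(df["condition"]) - set(VALID_CONDITIONS)
    if bad_cond:
        raise FormatError(f"{path}: unknown conditions {sorted(bad_cond)}")
    bad_assay = set(df["assay"]) - set(VALID_ASSAYS)
    if bad_assay:
        raise FormatError(f"{path}: unknown assays {sorted(bad_assay)}")
    df = df.assign(replicate=pd.to_numeric(df["replicate"], errors="raise"))
    for assay, grp in df.groupby("assay"):
        if grp["sample_id"].duplicated().any():
            raise FormatError(f"{path}: duplicate sample ids within assay {assay}")
    return df.reset_index(drop=True)


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def merge_assays(mrna: pd.DataFrame, mirna: pd.DataFrame
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Row-concatenate the two assay matrices over shared sample labels.

    Sample columns must match as sets (pairing by cell line, condition
    and replicate is encoded in the shared sample ids); feature
    namespaces must be disjoint.  Returns the merged matrix and a
    per-feature Series recording the assay of origin.
    """
    if len(mirna) == 0:
        origin = pd.Series("mRNA", index=mrna.index, name="assay")
        return mrna.copy(), origin
    if set(mrna.columns) != set(mirna.columns):
        odd = set(mrna.columns) ^ set(mirna.columns)
        raise ValueError(f"unmatched sample labels across assays: {sorted(odd)[:5]}")
    overlap = set(mrna.index) & set(mirna.index)
    if overlap:
        raise ValueError(f"feature ids shared across assays: {sorted(overlap)[:5]}")
    merged = pd.concat([mrna, mirna.loc[:, mrna.columns]])
    origin = pd.Series(
        ["mRNA"] * len(mrna) + ["miRNA"] * len(mirna),
        index=merged.index, name="assay",
    )
    return merged, origin


def read_network(path) -> RegulatoryNetwork:
    """Read an edge-list TSV into a validated network."""
    df = _read_tsv(path)
    required = {"source", "target", "source_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: edge list lacks columns {sorted(missing)}")
    out = df.loc[:, ["source", "target", "source_class"]].copy()
    sign_map = {"-1": -1, "+1": 1, "1": 1, "0": 0, "unknown": 0, "": 0}
    if "sign" in df.columns:
        parsed = df["sign"].map(sign_map)
        if parsed.isna().any():
            bad = df.loc[parsed.isna(), "sign"].iloc[0]
            raise FormatError(f"{path}: unparseable sign {bad!r}")
        out["sign"] = parsed.astype(int)
    for col in ("rho", "mi"):
        if col in df.columns:
            out[col] = pd.to_numeric(df[col].where(df[col] != "", np.nan),
                                     errors="raise")
    return RegulatoryNetwork(out)


def write_network(network: RegulatoryNetwork, path) -> None:
    network.edges.loc[:, list(EDGE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_gmt(path, background=None) -> GeneSetCollection:
    """Read a GMT file: one set per line (name, description, members)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, "
                                  "description and >= 1 member")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise FormatError(f"{path}:{ln}: duplicate set name {name!r}")
            if not members:
                raise FormatError(f"{path}:{ln}: set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, background=background,
                             descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
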