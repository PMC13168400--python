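"""End-to-end orchestration of the driver-activity analysis.

:func:`analyze` is the in-memory core: counts + sample table + network
(+ optional gene sets) in, a result bundle out.  :func:`run_pipeline`
wraps it with file I/O, per-stage logging, and a machine-readable
provenance record, driven by a :class:`PipelineConfig` (YAML/JSON).

Stage order: per-assay depth normalization -> merge -> low-expression
filter -> batch adjustment (cell line, preserving condition) -> PCA QC
-> group-mean edge correlation -> miRNA edge pruning -> sign resolution
-> MI weighting -> activity scores -> moderated DE and DA -> per-driver
target summary -> network-background enrichment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from . import __version__
from .activity import activity_scores, mi_weights
from .diffstats import call_da, call_de, fit_moderated
from .enrichment import GeneSetCollection, build_input_list, enrich
from .network import (RegulatoryNetwork, group_means, prune_mirna_edges,
                      resolve_signs, score_edges)
from .preprocess import batch_adjust, filter_low_expression, normalize_log2, pca_scores
from .synthetic import SimConfig, generate_network, ground_truth_frame, simulate_counts

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Thresholds and switches; defaults are the analysis' printed values."""

    alpha_de: float = 0.05
    lfc: float = 1.0
    alpha_da: float = 0.05
    target_z: float = 1.64
    filter_pct: float = 5.0
    filter_frac: float = 0.90
    min_targets: int = 1
    standardize_activity: bool = True
    batch_method: str = "eb"          # "eb" (ComBat) or "center"
    mi_estimator: str = "copula"      # or "binned"
    or_mode: str = "paper"            # or "standard"
    paired_correlations: bool = False  # rho over samples instead of group means

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_da"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lfc < 0 or self.target_z < 0:
            raise ValueError("thresholds must be non-negative")


def summarize_drivers(
    da: pd.DataFrame,
    de: pd.DataFrame,
    network: RegulatoryNetwork,
    z_thresh: float = 1.64,
) -> pd.DataFrame:
    """Per-driver regulation summary.

    For every driver in the DA table: regulon size, number of targets
    significantly up- (z >= +z_thresh) and down-regulated
    (z <= -z_thresh) in the expression contrast, the driver's DA z and
    adjusted p, and — where its own transcript was testable — its DE
    log2FC and adjusted p.
    """
    regs = network.regulons()
    classes = network.driver_class()
    rows = []
    for driver in da.index:
        if driver not in regs:
            logger.warning("summarize_drivers: %s absent from the network; skipped",
                           driver)
            continue
        targets = regs[driver]["target"]
        tz = de.loc[de.index.intersection(targets), "z"]
        rows.append({
            "driver": driver,
            "source_class": classes.get(driver, "NA"),
            "regulon_size": len(targets),
            "n_targets_up": int((tz >= z_thresh).sum()),
            "n_targets_down": int((tz <= -z_thresh).sum()),
            "da_z": da.loc[driver, "z"],
            "da_adj_p": da.loc[driver, "adj_p"],
            "da_significant": bool(da.loc[driver, "significant"])
            if "significant" in da.columns else np.nan,
            "de_log2fc": de.loc[driver, "effect"] if driver in de.index else np.nan,
            "de_adj_p": de.loc[driver, "adj_p"] if driver in de.index else np.nan,
        })
    return pd.DataFrame(rows)


def analyze(
    counts_mrna: pd.DataFrame,
    counts_mirna: pd.DataFrame,
    samples: pd.DataFrame,
    network: RegulatoryNetwork,
    gene_sets: GeneSetCollection | None = None,
    params: AnalysisParams | None = None,
) -> dict:
    """Run the full analysis in memory.

    Returns a dict with every intermediate and final artifact:
    ``expression`` (merged, filtered, batch-adjusted), ``norm_factors``,
    ``pca``, ``network`` (scored, pruned, weighted), ``activity``,
    ``de``, ``da``, ``driver_summary``, ``enrichment`` (None when no
    gene sets or no significant miRNA drivers), and ``stage_counts``.
    """
    params = params or AnalysisParams()
    counts: dict[str, int] = {}

    expr_mrna, nf_mrna = normalize_log2(counts_mrna)
    expr_mirna, nf_mirna = normalize_log2(counts_mirna)
    merged, origin = nio.merge_assays(expr_mrna, expr_mirna)
    counts["features_merged"] = len(merged)

    filtered, thresholds = filter_low_expression(
        merged, pct=params.filter_pct, frac=params.filter_frac)
    counts["features_filtered"] = len(filtered)

    meta = samples.drop_duplicates("sample_id").set_index("sample_id")
    adjusted = batch_adjust(filtered, meta, method=params.batch_method)
    pca = pca_scores(adjusted, n_components=min(2, *adjusted.shape))

    # Edge correlations and MI are read off the *unadjusted* (but
    # normalized and filtered) matrix: between-cell-line covariation is
    # the regulatory signal those statistics exploit, and batch
    # adjustment would strip it.  The differential contrasts below use
    # the adjusted matrix.
    if params.paired_correlations:
        profile = filtered
    else:
        profile = group_means(filtered, meta)
    scored = score_edges(network, profile)
    counts["edges_scored"] = scored.n_edges
    pruned = prune_mirna_edges(scored)
    counts["edges_pruned"] = pruned.n_edges
    signed = resolve_signs(pruned)
    weighted = mi_weights(filtered, signed, estimator=params.mi_estimator)
    counts["edges_final"] = weighted.n_edges

    act = activity_scores(adjusted, weighted,
                          standardize=params.standardize_activity,
                          min_targets=params.min_targets)
    counts["drivers_scored"] = len(act)

    de = call_de(fit_moderated(adjusted, meta),
                 alpha=params.alpha_de, lfc=params.lfc)
    da = call_da(fit_moderated(act, meta), alpha=params.alpha_da)
    counts["de_significant"] = int(de["significant"].sum())
    counts["da_significant"] = int(da["significant"].sum())

    summary = summarize_drivers(da, de, weighted, z_thresh=params.target_z)

    enrichment = None
    if gene_sets is not None:
        input_genes = build_input_list(da, weighted)
        if input_genes:
            background = gene_sets.background or frozenset(weighted.nodes())
            enrichment = enrich(input_genes, gene_sets, background,
                                alpha=0.05, or_mode=params.or_mode)
            counts["enriched_sets_significant"] = int(
                enrichment["significant"].sum())
        else:
            logger.info("analyze: no significant miRNA drivers — "
                        "enrichment skipped")

    return {
        "expression": adjusted,
        "norm_factors": {"mRNA": nf_mrna, "miRNA": nf_mirna},
        "filter_thresholds": thresholds,
        "assay_origin": origin,
        "pca": pca,
        "network": weighted,
        "activity": act,
        "de": de,
        "da": da,
        "driver_summary": summary,
        "enrichment": enrichment,
        "stage_counts": counts,
    }


# ---------------------------------------------------------------------------
# file-driven pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths, thresholds and switches for a file-driven run."""

    counts_mrna: str
    counts_mirna: str
    sample_table: str
    network: str
    out_dir: str
    gene_sets: str | None = None
    id_mapping: str | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        p = raw.pop("params", {})
        return cls(params=AnalysisParams(**p), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the analysis from files and persist every artifact.

    Writes (under ``config.out_dir``): expression.tsv, pca.tsv,
    network_weighted.tsv, activity.tsv, de.tsv, da.tsv,
    driver_summary.tsv, enrichment.tsv (when applicable), run.log and
    provenance.json.  Deterministic given inputs; re-running reproduces
    byte-identical tables.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("netdriver")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        mapping = (nio.read_id_mapping(config.id_mapping)
                   if config.id_mapping else None)
        counts_mrna = nio.read_counts(config.counts_mrna,
                                      aggregate_duplicates=True,
                                      id_mapping=mapping)
        counts_mirna = nio.read_counts(config.counts_mirna,
                                       aggregate_duplicates=True,
                                       id_mapping=mapping)
        samples = nio.read_sample_table(config.sample_table)
        network = nio.read_network(config.network)
        gene_sets = nio.read_gmt(config.gene_sets) if config.gene_sets else None

        result = analyze(counts_mrna, counts_mirna, samples, network,
                         gene_sets=gene_sets, params=config.params)

        nio.write_matrix(result["expression"], out_dir / "expression.tsv")
        result["pca"].to_csv(out_dir / "pca.tsv", sep="\t")
        nio.write_network(result["network"], out_dir / "network_weighted.tsv")
        nio.write_matrix(result["activity"], out_dir / "activity.tsv")
        for key in ("de", "da"):
            tbl = result[key].copy()
            tbl.insert(0, "feature_id", tbl.index)
            tbl.to_csv(out_dir / f"{key}.tsv", sep="\t", index=False)
        result["driver_summary"].to_csv(out_dir / "driver_summary.tsv",
                                        sep="\t", index=False)
        if result["enrichment"] is not None:
            result["enrichment"].to_csv(out_dir / "enrichment.tsv",
                                        sep="\t", index=False)

        cfg_dict = config.to_dict()
        provenance = {
            "netdriver_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
            "stage_counts": result["stage_counts"],
        }
        with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        result["provenance"] = provenance
        return result
    finally:
        root.removeHandler(handler)
        handler.close()


def simulate_to_dir(config: SimConfig, out_dir) -> dict[str, Path]:
    """Generate a synthetic study and write all its input files."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network = generate_network(config)
    mrna, mirna, samples, truth = simulate_counts(network, config)
    paths = {
        "counts_mrna": out_dir / "counts_mrna.tsv",
        "counts_mirna": out_dir / "counts_mirna.tsv",
        "sample_table": out_dir / "samples.tsv",
        "network": out_dir / "network.tsv",
        "ground_truth": out_dir / "ground_truth.tsv",
        "config": out_dir / "sim_config.yaml",
    }
    nio.write_matrix(mrna, paths["counts_mrna"])
    nio.write_matrix(mirna, paths["counts_mirna"])
    nio.write_sample_table(samples, paths["sample_table"])
    nio.write_network(network, paths["network"])
    ground_truth_frame(truth).to_csv(paths["ground_truth"], sep="\t", index=False)
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return paths
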