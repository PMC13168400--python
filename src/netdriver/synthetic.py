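"""Synthetic regulatory networks and count data with planted structure.

The generator emulates the design of a transcription-factor knockdown
study in two cell lines: a hub TF is depleted in half the samples, a
regulatory network of TFs and miRNAs acts on a pool of target genes,
and negative-binomial read counts are drawn per sample for an mRNA and
a miRNA assay (``n_cell_lines x 2 conditions x n_replicates`` samples
per assay, 16 with the defaults).

Three kinds of signal are planted, each recorded in
:class:`GroundTruth` so recovery can be scored:

* the **hub knockdown** — a log2 shift on the hub's own expression,
  propagated one hop to its direct targets with a fixed attenuation;
* **hidden drivers** — a subset of miRNAs whose *own* expression is
  untouched while all their targets shift by ``edge sign x
  hidden_activity_shift`` under knockdown (the regulatory-activity
  change a network method should detect and an expression test should
  miss);
* optional spike-ins — miRNA drivers with a shifted own expression
  (``expressed_driver_fraction``) and plain differentially expressed
  genes (``de_gene_fraction``), both off by default.

Cell-line batch effects enter as per-(batch, feature) location offsets
on the log2 mean and lognormal multipliers on the biological noise
scale.  Targets additionally track their regulators' cell-line offsets
(``regulatory_coupling``, signed, one hop): the steady-state
between-cell-line covariation that network edge scoring reads out.
All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .network import RegulatoryNetwork

HUB_ID = "TF_HUB"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-design and noise parameters for the generator.

    Defaults encode the two-cell-line knockdown design: 2 cell lines x
    2 conditions x 4 replicates = 16 samples per assay, 40 miRNA
    drivers of which a quarter are hidden drivers with a unit activity
    shift, and a strongly depleted hub TF.
    """

    n_tf: int = 20
    n_mirna: int = 40
    n_target_genes: int = 2000
    targets_per_driver: tuple[int, int] = (4, 30)
    n_cell_lines: int = 2
    n_conditions: int = 2            # fixed: control, knockdown
    n_replicates: int = 4
    hub_kd_log2_shift: float = -2.5
    hub_target_fraction: float = 0.3
    propagation_attenuation: float = 0.5
    hidden_driver_fraction: float = 0.25
    hidden_activity_shift: float = 1.0
    expressed_driver_fraction: float = 0.0
    expressed_driver_log2_shift: float = 1.5
    de_gene_fraction: float = 0.0
    de_gene_log2_shift: float = 2.0
    regulatory_coupling: float = 0.4
    batch_location_sd: float = 1.0
    batch_scale_sd: float = 0.3
    biological_sd: float = 0.2
    nb_dispersion: float = 0.1
    depth_range: tuple[int, int] = (800_000, 1_200_000)
    mirna_depth_range: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tf", "n_mirna", "n_target_genes", "n_cell_lines",
                     "n_replicates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_conditions != 2:
            raise ConfigError("n_conditions is fixed at 2 (control, knockdown)")
        lo, hi = self.targets_per_driver
        if not 1 <= lo <= hi:
            raise ConfigError("targets_per_driver must satisfy 1 <= min <= max")
        if hi > self.n_target_genes:
            raise ConfigError("targets_per_driver max exceeds n_target_genes")
        for name in ("hidden_driver_fraction", "expressed_driver_fraction",
                     "de_gene_fraction", "hub_target_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        dlo, dhi = self.depth_range
        if not 0 < dlo <= dhi:
            raise ConfigError("depth_range must satisfy 0 < min <= max")
        if self.mirna_depth_range is not None:
            mlo, mhi = self.mirna_depth_range
            if not 0 < mlo <= mhi:
                raise ConfigError("mirna_depth_range must satisfy 0 < min <= max")
        for name in ("batch_location_sd", "batch_scale_sd", "biological_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("targets_per_driver", "depth_range", "mirna_depth_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted signal labels for recovery scoring.

    ``hidden_drivers`` have a regulatory-activity shift but no shift on
    their own transcript; ``expression_shifted_features`` maps every
    feature with a non-zero true condition log2 shift (knockdown -
    control) to that shift; ``batch_offsets`` holds the per-(batch,
    feature) location offset and noise-scale multiplier.
    """

    hidden_drivers: frozenset[str]
    expression_shifted_features: dict[str, float]
    batch_offsets: pd.DataFrame = field(repr=False)
    activity_shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clash = {
            f for f in self.hidden_drivers
            if abs(self.expression_shifted_features.get(f, 0.0)) >= 1.0
        }
        if clash:
            raise ValueError(f"hidden drivers with own-expression shifts: "
                             f"{sorted(clash)}")


def _feature_ids(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    tfs = [f"TF{i:04d}" for i in range(1, config.n_tf + 1)]
    mirnas = [f"MIR{i:04d}" for i in range(1, config.n_mirna + 1)]
    genes = [f"G{i:05d}" for i in range(1, config.n_target_genes + 1)]
    return tfs, mirnas, genes


def generate_network(config: SimConfig) -> RegulatoryNetwork:
    """Random regulatory network with a knockdown hub.

    The hub TF regulates a fraction of the other TFs and of the miRNAs;
    every TF and miRNA regulates a regulon of target genes whose size is
    drawn uniformly from ``targets_per_driver``.  miRNA->gene edges are
    repressive (sign -1); TF edges are activating with probability 0.7.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    tfs, mirnas, genes = _feature_ids(config)
    lo, hi = config.targets_per_driver

    rows: list[tuple[str, str, str, int]] = []
    n_hub_tf = int(round(config.hub_target_fraction * len(tfs)))
    n_hub_mir = int(round(config.hub_target_fraction * len(mirnas)))
    hub_tf = rng.choice(tfs, size=n_hub_tf, replace=False)
    hub_mir = rng.choice(mirnas, size=n_hub_mir, replace=False)
    for tgt in list(hub_tf) + list(hub_mir):
        sign = -1 if rng.random() > 0.7 else 1
        rows.append((HUB_ID, tgt, "TF", sign))

    for driver, cls in [(t, "TF") for t in tfs] + [(m, "miRNA") for m in mirnas]:
        size = int(rng.integers(lo, hi + 1))
        targets = rng.choice(genes, size=size, replace=False)
        for tgt in targets:
            if cls == "miRNA":
                sign = -1
            else:
                sign = -1 if rng.random() > 0.7 else 1
            rows.append((driver, tgt, cls, sign))

    edges = pd.DataFrame(rows, columns=["source", "target", "source_class", "sign"])
    return RegulatoryNetwork(edges)


def _sample_table(config: SimConfig, assay: str) -> pd.DataFrame:
    rows = []
    for cl in range(1, config.n_cell_lines + 1):
        for cond in ("control", "knockdown"):
            for rep in range(1, config.n_replicates + 1):
                rows.append({
                    "sample_id": f"CL{cl}_{cond}_{rep}",
                    "cell_line": f"CL{cl}",
                    "condition": cond,
                    "replicate": rep,
                    "assay": assay,
                })
    return pd.DataFrame(rows)


def simulate_counts(
    network: RegulatoryNetwork,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw negative-binomial count matrices for both assays.

    Returns ``(mrna_counts, mirna_counts, sample_table, ground_truth)``.
    The sample table stacks the mRNA and miRNA rows; sample ids are
    shared across assays (same cell line, condition and replicate) so
    the matrices can be merged column-wise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tfs, mirnas, genes = _feature_ids(config)
    mrna_features = [HUB_ID] + tfs + genes
    edges = network.edges

    # --- true condition shifts (knockdown - control), log2 scale -------
    shifts: dict[str, float] = {}
    if config.hub_kd_log2_shift != 0.0:
        shifts[HUB_ID] = config.hub_kd_log2_shift
        hub_edges = edges[edges["source"] == HUB_ID]
        for _, e in hub_edges.iterrows():
            shifts[e["target"]] = (config.propagation_attenuation
                                   * config.hub_kd_log2_shift * e["sign"])

    hub_regulated = set(edges.loc[edges["source"] == HUB_ID, "target"])
    free_mirnas = [m for m in mirnas if m not in hub_regulated]
    n_hidden = int(round(config.hidden_driver_fraction * config.n_mirna))
    if n_hidden > len(free_mirnas):
        raise ConfigError("not enough hub-independent miRNAs to plant "
                          f"{n_hidden} hidden drivers")
    hidden = list(rng.choice(free_mirnas, size=n_hidden, replace=False))

    remaining = [m for m in free_mirnas if m not in hidden]
    n_expressed = int(round(config.expressed_driver_fraction * config.n_mirna))
    n_expressed = min(n_expressed, len(remaining))
    expressed = list(rng.choice(remaining, size=n_expressed, replace=False))

    activity_shifts: dict[str, float] = {}
    for mir in hidden:
        activity_shifts[mir] = config.hidden_activity_shift
        for _, e in edges[edges["source"] == mir].iterrows():
            shifts[e["target"]] = shifts.get(e["target"], 0.0) + (
                e["sign"] * config.hidden_activity_shift)
    for mir in expressed:
        own = config.expressed_driver_log2_shift * (1 if rng.random() < 0.5 else -1)
        shifts[mir] = own
        for _, e in edges[edges["source"] == mir].iterrows():
            shifts[e["target"]] = shifts.get(e["target"], 0.0) + (
                config.propagation_attenuation * own * e["sign"])

    if config.de_gene_fraction > 0:
        untouched = [g for g in genes if g not in shifts]
        n_de = int(round(config.de_gene_fraction * config.n_target_genes))
        n_de = min(n_de, len(untouched))
        for g in rng.choice(untouched, size=n_de, replace=False):
            shifts[g] = config.de_gene_log2_shift

    # --- batch structure ------------------------------------------------
    batches = [f"CL{i}" for i in range(1, config.n_cell_lines + 1)]
    all_features = mrna_features + mirnas
    feat_pos_all = {f: i for i, f in enumerate(all_features)}
    loc = rng.normal(0.0, config.batch_location_sd,
                     size=(len(batches), len(all_features)))
    scale = np.exp(rng.normal(0.0, config.batch_scale_sd,
                              size=(len(batches), len(all_features))))
    # steady-state regulatory coupling: a target's cell-line offset tracks
    # its regulators' cell-line offsets (signed, one hop) — this is the
    # between-cell-line covariation that edge correlation scoring reads
    if config.regulatory_coupling != 0.0:
        si = edges["source"].map(feat_pos_all).to_numpy()
        ti = edges["target"].map(feat_pos_all).to_numpy()
        sgn = edges["sign"].to_numpy(float)
        coupled = np.zeros_like(loc)
        for b in range(len(batches)):
            np.add.at(coupled[b], ti,
                      config.regulatory_coupling * sgn * loc[b, si])
        loc = loc + coupled
    batch_offsets = pd.DataFrame({
        "batch": np.repeat(batches, len(all_features)),
        "feature_id": np.tile(all_features, len(batches)),
        "location": loc.ravel(),
        "scale": scale.ravel(),
    })

    truth = GroundTruth(
        hidden_drivers=frozenset(hidden),
        expression_shifted_features={k: v for k, v in shifts.items() if v != 0.0},
        batch_offsets=batch_offsets,
        activity_shifts=activity_shifts,
    )

    # --- draw counts per assay ------------------------------------------
    feat_pos = feat_pos_all
    shift_vec = np.array([shifts.get(f, 0.0) for f in all_features])
    base = rng.normal(6.0, 1.5, size=len(all_features))

    def _draw(features: list[str], depth_range: tuple[int, int]) -> pd.DataFrame:
        table = _sample_table(config, "x")
        idx = [feat_pos[f] for f in features]
        n_samples = len(table)
        depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n_samples)
        cols = {}
        for j, row in table.iterrows():
            b = batches.index(row["cell_line"])
            is_kd = row["condition"] == "knockdown"
            mu = (base[idx]
                  + (shift_vec[idx] if is_kd else 0.0)
                  + loc[b, idx]
                  + rng.normal(0.0, config.biological_sd * scale[b, idx]))
            rel = np.exp2(mu)
            lam = depths[j] * rel / rel.sum()
            n_nb = 1.0 / config.nb_dispersion
            counts = rng.negative_binomial(n_nb, n_nb / (n_nb + lam))
            cols[row["sample_id"]] = counts
        out = pd.DataFrame(cols, index=pd.Index(features, name="feature_id"))
        return out

    mrna = _draw(mrna_features, config.depth_range)
    mirna = _draw(mirnas, config.mirna_depth_range or config.depth_range)
    samples = pd.concat(
        [_sample_table(config, "mRNA"), _sample_table(config, "miRNA")],
        ignore_index=True,
    )
    return mrna, mirna, samples, truth


def ground_truth_frame(truth: GroundTruth) -> pd.DataFrame:
    """Flatten a GroundTruth into a tidy feature-level table (for TSV)."""
    feats = sorted(set(truth.expression_shifted_features)
                   | set(truth.hidden_drivers) | set(truth.activity_shifts))
    return pd.DataFrame({
        "feature_id": feats,
        "hidden_driver": [f in truth.hidden_drivers for f in feats],
        "true_log2_shift": [truth.expression_shifted_features.get(f, 0.0)
                            for f in feats],
        "true_activity_shift": [truth.activity_shifts.get(f, 0.0) for f in feats],
    })
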