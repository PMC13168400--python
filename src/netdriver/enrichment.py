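"""Gene-set enrichment against a network background.

Over-representation of an input gene list (the targets of miRNA drivers
with significant differential activity) in each gene set of a GMT
collection, with the *network* genes as the statistical universe rather
than the whole genome.  The p-value is the one-sided Fisher exact
(hypergeometric tail) test; the odds ratio uses the whole-count form

    OR = (overlap * background) / (hallmark * input)

with ``background = N - (overlap + hallmark + input)`` where N is the
universe size — note this differs from the cross-product odds ratio of
the 2x2 table (which is available as ``or_mode="standard"``).  Sets are
ranked by the combined score ``-ln(p) * OR``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffstats import bh_adjust
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional background universe."""

    sets: dict[str, frozenset[str]]
    background: frozenset[str] | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if self.background is not None:
            self.background = frozenset(self.background)
            if not self.background:
                raise ValueError("background gene set is empty")

    def __len__(self) -> int:
        return len(self.sets)


def build_input_list(da_table: pd.DataFrame, network: RegulatoryNetwork) -> set[str]:
    """Union of target genes of DA-significant miRNA drivers.

    Only miRNA-class sources feed the list; an empty result signals the
    caller to skip enrichment.
    """
    if "significant" not in da_table.columns:
        raise ValueError("DA table lacks significance calls; run call_da first")
    sig = set(da_table.index[da_table["significant"]])
    edges = network.edges
    pick = (edges["source_class"] == "miRNA") & edges["source"].isin(sig)
    genes = set(edges.loc[pick, "target"])
    if not genes:
        logger.info("build_input_list: no significant miRNA drivers; "
                    "enrichment will be skipped")
    return genes


def paper_odds_ratio(overlap: int, hallmark: int, input_size: int,
                     n_universe: int) -> float:
    """Whole-count odds ratio against the network universe.

    ``background = N - (overlap + hallmark + input)``; a negative
    background (tiny universe) is floored at 0 with a warning, and a
    0/0 ratio is defined as 0 with a warning.
    """
    if min(overlap, hallmark, input_size, n_universe) < 0:
        raise ValueError("counts must be non-negative")
    if overlap > min(hallmark, input_size):
        raise ValueError("overlap cannot exceed the smaller list")
    background = n_universe - (overlap + hallmark + input_size)
    if background < 0:
        warnings.warn("negative background count floored at 0", stacklevel=2)
        background = 0
    num = overlap * background
    den = hallmark * input_size
    if den == 0:
        if num == 0:
            warnings.warn("0/0 odds ratio defined as 0", stacklevel=2)
            return 0.0
        return float("inf")
    return num / den


def standard_odds_ratio(overlap: int, hallmark: int, input_size: int,
                        n_universe: int) -> float:
    """Cross-product odds ratio (a*d)/(b*c) of the partitioned 2x2 table."""
    a = overlap
    b = input_size - overlap
    c = hallmark - overlap
    d = n_universe - input_size - hallmark + overlap
    if min(b, c, d) < 0:
        raise ValueError("inconsistent 2x2 counts")
    if b * c == 0:
        return float("inf") if a * d > 0 else 0.0
    return (a * d) / (b * c)


def fisher_p(overlap: int, hallmark: int, input_size: int, n_universe: int) -> float:
    """One-sided (enrichment) Fisher exact p: P(X >= overlap).

    X is hypergeometric — draws of size `input_size` from a universe of
    `n_universe` genes containing `hallmark` successes.
    """
    a = overlap
    b = input_size - overlap
    c = hallmark - overlap
    d = n_universe - input_size - hallmark + overlap
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent 2x2 counts")
    return float(hypergeom.sf(overlap - 1, n_universe, hallmark, input_size))


def enrich(
    input_genes,
    sets: GeneSetCollection,
    background,
    alpha: float = 0.05,
    or_mode: str = "paper",
) -> pd.DataFrame:
    """Score every gene set; one row per set, sorted by adjusted p.

    Input genes outside the background are dropped (logged); set members
    are intersected with the background.  Columns: ``overlap_gene``,
    ``hallmark_gene``, ``input_gene``, ``background_gene``, ``OR``,
    ``p``, ``adj_p``, ``combined_score``, ``significant``.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    input_genes = set(input_genes)
    dropped = input_genes - background
    if dropped:
        logger.info("enrich: dropped %d input genes outside the background",
                    len(dropped))
    input_genes &= background
    n_universe = len(background)
    or_fn = {"paper": paper_odds_ratio, "standard": standard_odds_ratio}[or_mode]

    rows = []
    for name in sorted(sets.sets):
        members = sets.sets[name] & background
        overlap = len(members & input_genes)
        n_set = len(members)
        n_input = len(input_genes)
        p = fisher_p(overlap, n_set, n_input, n_universe) if n_set else 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oddsr = or_fn(overlap, n_set, n_input, n_universe) if n_set else 0.0
        bg = max(n_universe - (overlap + n_set + n_input), 0)
        rows.append({
            "set_name": name,
            "overlap_gene": overlap,
            "hallmark_gene": n_set,
            "input_gene": n_input,
            "background_gene": bg,
            "OR": oddsr,
            "p": p,
            "combined_score": -np.log(p) * oddsr if np.isfinite(oddsr) else np.inf,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        out["adj_p"] = []
        out["significant"] = []
        return out
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["adj_p"] <= alpha
    out = out.sort_values(["adj_p", "p", "set_name"], kind="stable").reset_index(drop=True)
    return out[["set_name", "overlap_gene", "hallmark_gene", "input_gene",
                "background_gene", "OR", "p", "adj_p", "combined_score",
                "significant"]]
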