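"""Target-prediction post-processing: from predicted miRNA-mRNA binding
sites to per-category "connectivity" scores and the bipartite
miRNA-gene network.

The pipeline: (1) curated ("tarbase-like") records are kept only when
their validation score reaches ``tarbase_min_score`` (sequence-based
"starmir-like" predictions pass through); (2) sites below the minimum
logit probability are dropped; (3) multiple predicted sites of one miRNA
on one transcript collapse to a single hit; (4) per-gene hit counts
(distinct miRNAs) are averaged over the genes of each pathway category —
genes with zero hits stay in the denominator — giving the category's
connectivity score.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .datamodel import INTERACTION_CATEGORIES, InteractionTable, ValidationError
from .fixtures import gene_panel, resilience_mirnas
from .network import PhenotypeNetwork

__all__ = [
    "ConnectivityResult",
    "filter_validated",
    "dedup_hits",
    "connectivity",
    "bipartite_network",
    "resilience_fixture",
    "gene_panel",
]


def filter_validated(t: InteractionTable, min_score: float = 0.8) -> InteractionTable:
    """Keep curated records with validation score >= min_score (inclusive).

    Sequence-prediction records ('starmir-like') pass through unchanged;
    a curated record with no score is a validation error.
    """
    df = t.df
    curated = df["source"] == "tarbase-like"
    if curated.any() and df.loc[curated, "source_score"].isna().any():
        bad = df.loc[curated & df["source_score"].isna(), ["mirna", "gene"]]
        raise ValidationError(
            f"tarbase-like record(s) missing source_score: {bad.to_records(index=False).tolist()}"
        )
    keep = ~curated | (df["source_score"] >= min_score)
    return InteractionTable(df[keep].reset_index(drop=True))


def dedup_hits(t: InteractionTable) -> pd.DataFrame:
    """Collapse multiple sites on one transcript to one (mirna, gene) hit."""
    if len(t) == 0:
        return pd.DataFrame(columns=["mirna", "gene"])
    return (
        t.df[["mirna", "gene"]]
        .drop_duplicates()
        .sort_values(["gene", "mirna"], kind="mergesort")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class ConnectivityResult:
    """Outcome of the connectivity scoring."""

    hits: pd.DataFrame  # deduplicated surviving (mirna, gene) pairs
    gene_hit_counts: pd.Series  # distinct miRNAs per panel gene (0 included)
    category_scores: pd.Series  # mean hit count over each category's genes
    surviving: InteractionTable
    logit_min: float

    @property
    def total_hits(self) -> int:
        return len(self.hits)


def connectivity(
    t: InteractionTable, panel: pd.DataFrame | None = None, logit_min: float = 0.5
) -> ConnectivityResult:
    """Score each pathway category by its gene-count-adjusted hit total.

    Sites with logit probability below ``logit_min`` are dropped, hits
    deduplicated per (miRNA, gene), and each category scored as
    (total hits on the category's genes) / (number of panel genes in the
    category).  Zero-hit genes still count in the denominator.
    """
    if panel is None:
        panel = gene_panel()
    if len(panel) == 0 or panel["gene"].duplicated().any():
        raise ValidationError("panel must be non-empty with unique gene symbols")
    present = set(panel["category"])
    bad = present - set(INTERACTION_CATEGORIES)
    if bad:
        raise ValidationError(f"unknown panel category: {sorted(bad)}")
    extra = set(t.df["gene"]) - set(panel["gene"])
    if extra:
        raise ValidationError(f"interactions reference genes outside the panel: {sorted(extra)}")
    surviving = InteractionTable(
        t.df[t.df["logit_prob"] >= logit_min].reset_index(drop=True)
    )
    hits = dedup_hits(surviving)
    per_gene = hits.groupby("gene").size() if len(hits) else pd.Series(dtype=int)
    gene_hit_counts = (
        panel.set_index("gene")
        .assign(hits=lambda d: per_gene.reindex(d.index).fillna(0).astype(int))["hits"]
    )
    cat = panel.set_index("gene")["category"]
    scores = gene_hit_counts.groupby(cat).mean()
    scores = scores.reindex(sorted(present))
    scores.name = "connectivity"
    return ConnectivityResult(hits, gene_hit_counts, scores, surviving, logit_min)


def bipartite_network(res: ConnectivityResult, panel: pd.DataFrame | None = None) -> PhenotypeNetwork:
    """Bipartite gene-miRNA graph of the surviving deduplicated hits.

    Every panel gene appears as a node (isolated when it has no hits),
    carrying its category and hit count; edges carry the maximum logit
    probability among the collapsed sites as weight.
    """
    if panel is None:
        panel = gene_panel()
    g = nx.Graph()
    for row in panel.itertuples():
        g.add_node(
            row.gene,
            kind="gene",
            sign=None,
            category=row.category,
            hits=int(res.gene_hit_counts.get(row.gene, 0)),
        )
    best = (
        res.surviving.df.groupby(["mirna", "gene"])["logit_prob"].max()
        if len(res.surviving)
        else pd.Series(dtype=float)
    )
    for row in res.hits.itertuples():
        if row.mirna not in g:
            g.add_node(row.mirna, kind="mirna", sign=None)
        lp = float(best.loc[(row.mirna, row.gene)])
        g.add_edge(row.mirna, row.gene, weight=lp, rho=lp, p=float("nan"))
    return PhenotypeNetwork(g)


def resilience_fixture() -> list[tuple[str, str]]:
    """The 12 resilience-related miRNAs as (mirna_id, direction) pairs."""
    return list(resilience_mirnas().itertuples(index=False, name=None))
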