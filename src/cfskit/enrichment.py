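"""Term enrichment and functional-network assembly for interactor sets.

The enrichment statistic is the upper-tail hypergeometric probability
P[X >= k] of drawing ``k`` term members in a selection of ``n`` genes
from a universe of ``N`` genes of which ``K`` carry the term, with
Benjamini-Hochberg control across tested terms.  The network step joins
classified interactors through a user-supplied confidence-scored edge
table (STRING-style), keeping edges at or above a minimum confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from cfskit.interactome import InteractorCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermAnnotation:
    """A gene-set annotation term (e.g. a GO term)."""

    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty gene set")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    fold_enrichment: float
    p_value: float
    q_value: float
    significant: bool


def read_gene_term_tsv(path) -> list[TermAnnotation]:
    """Two/three-column TSV: gene, term_id[, term_name]."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gene, term = str(row[0]).upper(), str(row[1])
        terms.setdefault(term, set()).add(gene)
        if len(row) > 2 and isinstance(row[2], str):
            names.setdefault(term, row[2])
    return [
        TermAnnotation(term_id=t, term_name=names.get(t, t), genes=frozenset(g))
        for t, g in sorted(terms.items())
    ]


def read_gmt(path) -> list[TermAnnotation]:
    """GMT format: term <tab> description <tab> gene1 <tab> gene2 ..."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append(
                TermAnnotation(
                    term_id=parts[0],
                    term_name=parts[1] or parts[0],
                    genes=frozenset(g for g in parts[2:] if g),
                )
            )
    return out


def read_annotations(path) -> list[TermAnnotation]:
    if str(path).endswith(".gmt"):
        return read_gmt(path)
    return read_gene_term_tsv(path)


def annotation_universe(terms: Iterable[TermAnnotation]) -> frozenset[str]:
    genes: set[str] = set()
    for t in terms:
        genes |= t.genes
    return frozenset(genes)


def hypergeom_enrichment(
    selection: Iterable[str],
    universe: Iterable[str],
    terms: Sequence[TermAnnotation],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in ``selection``.

    ``selection`` must be a subset of ``universe``; term gene sets are
    intersected with the universe before testing, and terms that vanish
    under the intersection are skipped (logged).  Results are sorted by
    raw p ascending with q-values from the BH step-up over all tested
    terms.
    """
    sel = {g.upper() for g in selection}
    uni = {g.upper() for g in universe}
    stray = sel - uni
    if stray:
        raise ValueError(
            f"selection contains {len(stray)} genes outside the universe: "
            f"{sorted(stray)[:10]}"
        )
    N, n = len(uni), len(sel)
    results = []
    for term in terms:
        in_universe = term.genes & uni
        K = len(in_universe)
        if K == 0:
            logger.info("term %s has no genes in the universe; skipped", term.term_id)
            continue
        k = len(in_universe & sel)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n else float("nan")
        results.append((term, k, K, p, fold))
    if not results:
        return []
    reject, qvals, _, _ = multipletests(
        [r[3] for r in results], alpha=alpha, method="fdr_bh"
    )
    out = [
        EnrichmentResult(
            term_id=term.term_id,
            term_name=term.term_name,
            k=k,
            K=K,
            n=n,
            N=N,
            fold_enrichment=fold,
            p_value=p,
            q_value=float(q),
            significant=bool(rej),
        )
        for (term, k, K, p, fold), q, rej in zip(results, qvals, reject)
    ]
    return sorted(out, key=lambda r: (r.p_value, r.term_id))


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def read_edges(path) -> pd.DataFrame:
    """Three-column TSV (geneA, geneB, score); malformed rows dropped."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected three columns (geneA, geneB, score)")
    df = df.iloc[:, :3]
    df.columns = ["gene_a", "gene_b", "score"]
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    bad = df["score"].isna() | (df["score"] < 0) | (df["score"] > 1)
    if bad.any():
        logger.warning("dropped %d malformed edge rows", int(bad.sum()))
    df = df[~bad].copy()
    df["gene_a"] = df["gene_a"].str.upper()
    df["gene_b"] = df["gene_b"].str.upper()
    return df


def build_network(
    calls: Sequence[InteractorCall],
    edges: pd.DataFrame,
    min_score: float = 0.4,
) -> nx.Graph:
    """Functional network over called interactors.

    Nodes are genes called ``potential_interactor`` or ``aph_induced``
    (isolated ones included); edges are kept iff both endpoints are call
    genes and the confidence score is at least ``min_score``.  Node
    attributes carry the enrichment level (median log2 H/M) and the
    APH-induced flag, mirroring node color/shape in a network figure.
    """
    g = nx.Graph(min_score=float(min_score))
    for c in calls:
        if c.tier in ("potential_interactor", "aph_induced"):
            g.add_node(
                c.gene,
                median_log2_hm=float(c.median_log2_hm),
                aph_induced=bool(c.tier == "aph_induced"),
            )
    nodes = set(g.nodes)
    n_dropped = 0
    for row in edges.itertuples(index=False):
        a, b, score = row.gene_a, row.gene_b, float(row.score)
        if score >= min_score and a in nodes and b in nodes and a != b:
            g.add_edge(a, b, score=score)
        else:
            n_dropped += 1
    logger.info(
        "network: %d nodes, %d edges (%d edge rows dropped)",
        g.number_of_nodes(),
        g.number_of_edges(),
        n_dropped,
    )
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
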