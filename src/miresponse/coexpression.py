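"""Bipartite miRNA-target co-expression network.

Candidate miRNA->gene pairs are the intersection of two prediction sources
(kept only when both programs agree). An edge enters the network when both
endpoints are differentially expressed and the pair is anti-correlated
across samples: by default Pearson r < 0 with correlation p < 0.05 and
opposite differential-expression direction, each clause toggleable.
The key miRNA of the network is the one with the largest degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .diffexpr import DEResult
from .io import ExpressionMatrix, TargetPairTable

logger = logging.getLogger(__name__)


def intersect_predictions(table_a: TargetPairTable,
                          table_b: TargetPairTable) -> set[tuple[str, str]]:
    """Pairs predicted by both sources (order-independent set intersection)."""
    if len(table_a.pairs) == 0 or len(table_b.pairs) == 0:
        raise ValueError("both prediction tables must be non-empty")
    return table_a.pair_set() & table_b.pair_set()


@dataclass
class CoexpressionNetwork:
    """Bipartite miRNA-gene graph with DE attributes and correlation edges."""

    graph: nx.Graph
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mirna_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "miRNA"]

    @property
    def gene_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "mRNA"]

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"mirna_id": u if self.graph.nodes[u]["kind"] == "miRNA" else v,
                 "gene_id": v if self.graph.nodes[u]["kind"] == "miRNA" else u,
                 "pearson_r": d["pearson_r"], "corr_p": d["corr_p"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["mirna_id", "gene_id",
                                           "pearson_r", "corr_p"])


def build_coexpression_network(pairs: set[tuple[str, str]],
                               de_mirnas: list[DEResult],
                               de_genes: list[DEResult],
                               mirna_matrix: ExpressionMatrix,
                               mrna_matrix: ExpressionMatrix,
                               corr_p_max: float = 0.05,
                               require_negative: bool = True,
                               require_corr_p: bool = True,
                               require_opposite_direction: bool = True,
                               ) -> CoexpressionNetwork:
    """Build the miRNA-target co-expression network.

    An edge (m, g) exists iff m and g are in the significant DE sets, (m, g)
    is a predicted pair, and the anti-correlation rule holds. Correlation is
    Pearson's r over all samples pooled across both groups. Pairs that
    reference a feature missing from its matrix are logged and skipped.
    """
    if list(mirna_matrix.sample_ids) != list(mrna_matrix.sample_ids):
        raise ValueError("miRNA and mRNA matrices must share the sample set")
    de_m = {r.feature_id: r for r in de_mirnas}
    de_g = {r.feature_id: r for r in de_genes}
    g = nx.Graph()
    skipped: list[tuple[str, str]] = []
    for m, t in sorted(pairs):
        if m not in de_m or t not in de_g:
            continue
        if m not in mirna_matrix.data.index or t not in mrna_matrix.data.index:
            logger.warning("pair (%s, %s) references a missing feature; skipped", m, t)
            skipped.append((m, t))
            continue
        xm = mirna_matrix.data.loc[m].to_numpy(dtype=float)
        xt = mrna_matrix.data.loc[t].to_numpy(dtype=float)
        r, p = scipy.stats.pearsonr(xm, xt)
        if require_negative and not r < 0:
            continue
        if require_corr_p and not p < corr_p_max:
            continue
        if require_opposite_direction and de_m[m].direction == de_g[t].direction:
            continue
        for node, res, kind in ((m, de_m[m], "miRNA"), (t, de_g[t], "mRNA")):
            g.add_node(node, kind=kind, direction=res.direction,
                       log2fc=res.log2fc, p_value=res.p_value)
        g.add_edge(m, t, pearson_r=float(r), corr_p=float(p))
    return CoexpressionNetwork(graph=g, skipped_pairs=skipped)


def key_mirna(network: CoexpressionNetwork) -> list[tuple[str, int]]:
    """miRNAs ranked by degree (desc), then |log2fc| (desc), then id.

    The head of the list is the key miRNA — the one contributing to the most
    target genes in the network.
    """
    mirnas = network.mirna_nodes
    if not mirnas:
        raise ValueError("network has no miRNA nodes")
    ranked = sorted(
        mirnas,
        key=lambda m: (-network.degree(m),
                       -abs(network.graph.nodes[m]["log2fc"]), m))
    return [(m, network.degree(m)) for m in ranked]
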