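"""Candidate biomarker panel assembly.

The two networks are integrated: the top edge-betweenness interactions of
the gene network nominate anchor genes, and for each anchor gene the most
significantly dysregulated upstream miRNA in the co-expression network
(smallest DE p-value; ties by larger |log2FC|, then id) enters the panel.
Panel size is emergent — anchors sharing a best miRNA are de-duplicated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .coexpression import CoexpressionNetwork
from .diffexpr import DEResult
from .io import ExpressionMatrix


class SelectionError(RuntimeError):
    """Raised when no anchor gene has any upstream miRNA."""


def key_interaction_genes(edge_report: list[tuple[tuple[str, str], float]],
                          top_k_edges: int = 2) -> list[str]:
    """Endpoint genes of the top-k edges by betweenness; cutoff ties included.

    Genes are returned in edge-rank order (then within-edge order),
    de-duplicated.
    """
    if not edge_report:
        raise ValueError("edge report is empty")
    if top_k_edges < 1:
        raise ValueError("top_k_edges must be >= 1")
    ranked = sorted(edge_report, key=lambda kv: (-kv[1], kv[0]))
    k = min(top_k_edges, len(ranked))
    cutoff = ranked[k - 1][1]
    genes: list[str] = []
    for (a, b), score in ranked:
        if score < cutoff:
            break
        for g in (a, b):
            if g not in genes:
                genes.append(g)
    return genes


@dataclass
class BiomarkerPanel:
    """Ordered candidate miRNA panel with provenance."""

    members: list[dict]                 # mirna_id, anchor_gene_id, log2fc, p_value
    key_interactions: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    skipped_genes: list[str] = field(default_factory=list)
    selection_rule: str = "min-p; tie |log2fc| desc, id asc; dedup by anchor rank"

    @property
    def mirna_ids(self) -> list[str]:
        return [m["mirna_id"] for m in self.members]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.members,
                            columns=["mirna_id", "anchor_gene_id",
                                     "log2fc", "p_value"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "members": self.members,
            "key_interactions": [[list(e), s] for e, s in self.key_interactions],
            "skipped_genes": self.skipped_genes,
            "selection_rule": self.selection_rule,
        }, indent=2))


def select_upstream_mirnas(genes: list[str],
                           coexp: CoexpressionNetwork,
                           de_results: list[DEResult],
                           key_interactions=None) -> BiomarkerPanel:
    """Pick each anchor gene's most significant upstream miRNA.

    Anchor genes without any incident miRNA edge are reported and skipped; a
    selection with no usable anchor at all is an error. A miRNA anchored by
    several genes appears once, keeping its first (highest-ranked) anchor.
    """
    de = {r.feature_id: r for r in de_results}
    members: list[dict] = []
    seen: set[str] = set()
    skipped: list[str] = []
    for gene in genes:
        if gene not in coexp.graph:
            skipped.append(gene)
            continue
        mirnas = [n for n in coexp.graph.neighbors(gene)
                  if coexp.graph.nodes[n]["kind"] == "miRNA"]
        if not mirnas:
            skipped.append(gene)
            continue
        best = min(mirnas,
                   key=lambda m: (de[m].p_value, -abs(de[m].log2fc), m))
        if best in seen:
            continue
        seen.add(best)
        members.append({"mirna_id": best, "anchor_gene_id": gene,
                        "log2fc": de[best].log2fc, "p_value": de[best].p_value})
    if not members:
        raise SelectionError("no anchor gene has an upstream miRNA")
    return BiomarkerPanel(members=members,
                          key_interactions=list(key_interactions or []),
                          skipped_genes=skipped)


def panel_feature_matrix(panel: BiomarkerPanel,
                         mirna_matrix: ExpressionMatrix) -> pd.DataFrame:
    """Samples x panel matrix of raw levels (scaling is the classifier's job)."""
    missing = [m for m in panel.mirna_ids if m not in mirna_matrix.data.index]
    if missing:
        raise ValueError(f"panel miRNAs missing from the matrix: {missing}")
    return mirna_matrix.data.loc[panel.mirna_ids].T.copy()
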