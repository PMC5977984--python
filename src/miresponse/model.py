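"""Model/Results facade over the biomarker-discovery pipeline.

`ResponseBiomarkerModel` holds the cohort data (paired miRNA/mRNA log2
matrices, group labels, two target-prediction tables and an interaction
table) plus a :class:`~miresponse.io.RunConfig`; ``fit()`` executes the
whole discovery chain — RVM-moderated differential screen, prediction
intersection, anti-correlated co-expression network, median-filtered
interaction network with centrality/hub/MCL/edge-betweenness analysis,
panel assembly, repeated cross-validated RBF-SVM — and returns a
`ResponseBiomarkerResults` carrying every stage's output and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import classifier, coexpression, diffexpr, panel as panel_mod, topology
from .io import (
    ExpressionMatrix,
    InteractionTable,
    RunConfig,
    SampleAnnotation,
    TargetPairTable,
    check_annotations,
)


class StageError(RuntimeError):
    """A pipeline stage failed; `.stage` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ResponseBiomarkerModel:
    """Discovery-cohort model for circulating miRNA response biomarkers."""

    def __init__(self,
                 mirna: ExpressionMatrix,
                 mrna: ExpressionMatrix,
                 annotations: Sequence[SampleAnnotation],
                 pairs_a: TargetPairTable,
                 pairs_b: TargetPairTable,
                 interactions: InteractionTable,
                 config: RunConfig | None = None,
                 gene_sets: dict[str, set[str]] | None = None):
        self.mirna = mirna
        self.mrna = mrna
        self.annotations = list(annotations)
        self.pairs_a = pairs_a
        self.pairs_b = pairs_b
        self.interactions = interactions
        self.config = config or RunConfig()
        self.gene_sets = gene_sets
        check_annotations(mirna, self.annotations)
        check_annotations(mrna, self.annotations)

    @classmethod
    def from_dataframes(cls, mirna_df: pd.DataFrame, mrna_df: pd.DataFrame,
                        groups: dict[str, str], pairs_a: pd.DataFrame,
                        pairs_b: pd.DataFrame, interactions: pd.DataFrame,
                        config: RunConfig | None = None,
                        **kwargs) -> "ResponseBiomarkerModel":
        ann = [SampleAnnotation(s, g) for s, g in groups.items()]
        return cls(
            ExpressionMatrix(mirna_df, feature_kind="miRNA"),
            ExpressionMatrix(mrna_df, feature_kind="mRNA"),
            ann,
            TargetPairTable(pairs_a.assign(source="A")
                            if "source" not in pairs_a else pairs_a),
            TargetPairTable(pairs_b.assign(source="B")
                            if "source" not in pairs_b else pairs_b),
            InteractionTable(interactions),
            config=config, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self, compute_single_marker_cv: bool = True) -> "ResponseBiomarkerResults":
        cfg = self.config
        q_max = cfg.q_max if cfg.fdr_mode == "gate" else None

        # 1. differential expression (RVM moderated t) per feature kind
        try:
            de_m_all = self._run_de(self.mirna)
            de_g_all = self._run_de(self.mrna)
            up_m, down_m = diffexpr.screen_de(de_m_all, cfg.log2fc_min,
                                              cfg.p_max, q_max)
            up_g, down_g = diffexpr.screen_de(de_g_all, cfg.log2fc_min,
                                              cfg.p_max, q_max)
        except (diffexpr.FitError, ValueError) as exc:
            raise StageError("differential_expression", str(exc)) from exc
        de_mirnas, de_genes = up_m + down_m, up_g + down_g
        if not de_mirnas or not de_genes:
            raise StageError("differential_expression",
                             "no significant features at the configured "
                             "thresholds; nothing to build networks from")

        # 2. prediction intersection + co-expression network
        try:
            pair_set = coexpression.intersect_predictions(self.pairs_a,
                                                          self.pairs_b)
            clauses = cfg.corr_rule.split("+")
            coexp = coexpression.build_coexpression_network(
                pair_set, de_mirnas, de_genes, self.mirna, self.mrna,
                corr_p_max=cfg.corr_p_max,
                require_negative="negative" in clauses,
                require_corr_p="p" in clauses,
                require_opposite_direction="direction" in clauses)
        except ValueError as exc:
            raise StageError("coexpression_network", str(exc)) from exc
        if coexp.graph.number_of_edges() == 0:
            raise StageError("coexpression_network",
                             "no anti-correlated DE pairs survived")

        # 3. interaction topology
        de_gene_ids = [r.feature_id for r in de_genes]
        try:
            gene_net = topology.filter_by_median_score(self.interactions,
                                                       de_gene_ids)
            report = topology.topology_report(gene_net)
            partition = topology.mcl(gene_net, cfg.mcl_inflation,
                                     cfg.mcl_expansion, cfg.mcl_prune_min,
                                     cfg.mcl_max_iter, cfg.mcl_tol)
            enrichment = None
            if self.gene_sets:
                enrichment = topology.enrich_modules(
                    partition, self.gene_sets, set(gene_net.nodes()))
        except ValueError as exc:
            raise StageError("interaction_topology", str(exc)) from exc

        # 4. panel selection
        try:
            anchors = panel_mod.key_interaction_genes(report.edges,
                                                      cfg.top_k_edges)
            biopanel = panel_mod.select_upstream_mirnas(
                anchors, coexp, de_m_all,
                key_interactions=report.edges[:cfg.top_k_edges])
        except (ValueError, panel_mod.SelectionError) as exc:
            raise StageError("biomarker_selection", str(exc)) from exc

        # 5. cross-validated classification on the panel
        features = panel_mod.panel_feature_matrix(biopanel, self.mirna)
        mapping = check_annotations(self.mirna, self.annotations)
        y = np.array([classifier.RESPONDER if mapping[s] == "responder"
                      else classifier.NON_RESPONDER
                      for s in features.index])
        spec = classifier.ModelSpec(c=cfg.svm_c, gamma=cfg.svm_gamma,
                                    scale_mode=cfg.scale_mode)
        try:
            cv_report = classifier.kfold_cv(features.to_numpy(), y,
                                            k=cfg.cv_k, repeats=cfg.cv_repeats,
                                            spec=spec, seed=cfg.seed)
        except (ValueError, RuntimeError) as exc:
            raise StageError("response_classifier", str(exc)) from exc

        single_cv = None
        if compute_single_marker_cv and features.shape[1] > 1:
            rows = {}
            for mid in features.columns:
                rep = classifier.kfold_cv(
                    features[[mid]].to_numpy(), y, k=cfg.cv_k,
                    repeats=cfg.cv_repeats, spec=spec, seed=cfg.seed)
                rows[mid] = {"accuracy": rep.mean_accuracy,
                             "auc": rep.mean_auc}
            single_cv = pd.DataFrame(rows).T

        return ResponseBiomarkerResults(
            model=self, de_mirnas_all=de_m_all, de_genes_all=de_g_all,
            de_mirnas=de_mirnas, de_genes=de_genes,
            predicted_pairs=pair_set, coexpression=coexp,
            gene_network=gene_net, topology=report, partition=partition,
            enrichment=enrichment, panel=biopanel,
            panel_features=features, labels=y, cv_report=cv_report,
            single_marker_cv=single_cv)

    def _run_de(self, matrix: ExpressionMatrix) -> list[diffexpr.DEResult]:
        s2, d, _, _ = diffexpr.pooled_variances(matrix, self.annotations)
        prior = diffexpr.fit_rvm_prior(s2, d)
        return diffexpr.rvm_t_test(matrix, self.annotations, prior)


@dataclass
class ResponseBiomarkerResults:
    """Everything the fitted pipeline produced."""

    model: ResponseBiomarkerModel
    de_mirnas_all: list
    de_genes_all: list
    de_mirnas: list
    de_genes: list
    predicted_pairs: set
    coexpression: coexpression.CoexpressionNetwork
    gene_network: nx.Graph
    topology: topology.TopologyReport
    partition: topology.ModulePartition
    enrichment: pd.DataFrame | None
    panel: panel_mod.BiomarkerPanel
    panel_features: pd.DataFrame
    labels: np.ndarray
    cv_report: classifier.CVReport
    single_marker_cv: pd.DataFrame | None = None

    @property
    def panel_mirnas(self) -> list[str]:
        return self.panel.mirna_ids

    def key_mirnas(self) -> list[tuple[str, int]]:
        return coexpression.key_mirna(self.coexpression)

    def evaluate(self, features: np.ndarray, labels: np.ndarray) -> dict:
        """Train on the full discovery cohort, test on an independent set."""
        spec = classifier.ModelSpec(c=self.model.config.svm_c,
                                    gamma=self.model.config.svm_gamma,
                                    scale_mode=self.model.config.scale_mode)
        trained = classifier.train_svm_rbf(self.panel_features.to_numpy(),
                                           self.labels, spec)
        pred, dec = classifier.predict(trained, features)
        counts = classifier.ConfusionCounts.from_labels(labels, pred)
        sens, specificity, acc = classifier.metrics(counts)
        _, auc = classifier.roc_auc(dec, labels)
        return {"counts": counts, "sensitivity": sens,
                "specificity": specificity, "accuracy": acc, "auc": auc}

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Circulating miRNA response-biomarker discovery",
            "=" * 54,
            f"Samples: {len(self.labels)} "
            f"({int(np.sum(self.labels == 1))} responders / "
            f"{int(np.sum(self.labels == -1))} non-responders)",
            f"DE screen: |log2FC| > {cfg.log2fc_min}, p < {cfg.p_max} (RVM t-test)",
            f"  miRNAs: {len(self.de_mirnas)} significant "
            f"({sum(r.log2fc > 0 for r in self.de_mirnas)} up / "
            f"{sum(r.log2fc < 0 for r in self.de_mirnas)} down) "
            f"of {len(self.de_mirnas_all)}",
            f"  mRNAs:  {len(self.de_genes)} significant "
            f"({sum(r.log2fc > 0 for r in self.de_genes)} up / "
            f"{sum(r.log2fc < 0 for r in self.de_genes)} down) "
            f"of {len(self.de_genes_all)}",
            f"Predicted pairs (both sources): {len(self.predicted_pairs)}",
            f"Co-expression network: {len(self.coexpression.mirna_nodes)} miRNAs, "
            f"{len(self.coexpression.gene_nodes)} genes, "
            f"{self.coexpression.graph.number_of_edges()} anti-correlated edges",
            f"Interaction network: {self.gene_network.number_of_nodes()} genes, "
            f"{self.gene_network.number_of_edges()} edges (score > median)",
            f"  hub genes (all features > median): "
            f"{', '.join(self.topology.hub_genes()) or 'none'}",
            f"  MCL modules: sizes "
            f"{sorted(self.partition.module_sizes.values(), reverse=True)}",
            f"  top edge betweenness: "
            f"{self.topology.edges[0][0]} = {self.topology.edges[0][1]:.3g}",
            f"Panel ({len(self.panel_mirnas)} miRNAs): "
            f"{', '.join(self.panel_mirnas)}",
            f"Cross-validation ({cfg.cv_k}-fold x {cfg.cv_repeats}):",
            f"  accuracy    {self.cv_report.mean_accuracy:.4f}",
            f"  sensitivity {self.cv_report.mean_sensitivity:.4f}",
            f"  specificity {self.cv_report.mean_specificity:.4f}",
            f"  AUC         {self.cv_report.mean_auc:.4f}",
        ]
        if self.single_marker_cv is not None:
            lines.append("Single-marker CV AUC:")
            for mid, row in self.single_marker_cv.iterrows():
                lines.append(f"  {mid:<16s} {row['auc']:.4f}")
        return "\n".join(lines)
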