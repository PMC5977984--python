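"""Synthetic two-group cohorts with planted ground truth.

The generator emulates a small clinical discovery cohort profiled on log2
expression microarrays: two groups of a handful of samples each, additive
Gaussian noise on the log2 scale, a small set of planted miRNAs carrying a
group-level log2 fold change, target genes anti-correlated with their
planted miRNA, decoy prediction pairs split across two sources (so that the
source intersection removes them), and a gene-gene interaction graph with
two dense communities joined by a single high-betweenness bridge edge.

All randomness comes from ``numpy.random.default_rng`` (PCG64) seeded from
the spec, so generation is a pure function of ``(spec, seed)``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    InteractionTable,
    SampleAnnotation,
    TargetPairTable,
)


class SpecError(ValueError):
    """Raised for an internally inconsistent synthetic-cohort specification."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the reference study conditions: 6 responders vs 6
    non-responders, 4 planted miRNAs with |log2 fold change| Delta = 1.5,
    near-deterministic miRNA->target coupling beta = 1 and log2-scale noise
    sigma_e = 0.3.
    """

    n_responders: int = 6
    n_nonresponders: int = 6
    n_mirnas: int = 60
    n_genes: int = 150
    planted_mirnas: int = 4
    delta: float = 1.5            # |log2 FC| of each planted miRNA (sign alternates)
    beta: float = 1.0             # target = baseline - beta * centered miRNA + noise
    sigma_e: float = 0.3          # log2-scale noise sd
    targets_per_mirna: int = 5
    decoy_pair_fraction: float = 0.5
    bridge_module_sizes: tuple[int, int] = (5, 4)
    background_edges: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_mirnas > self.n_mirnas:
            raise SpecError("planted_mirnas exceeds n_mirnas")
        if self.sigma_e <= 0:
            raise SpecError("sigma_e must be positive")
        if self.planted_mirnas > 0 and self.delta == 0:
            raise SpecError("delta must be non-zero for planted features")
        if self.planted_mirnas * self.targets_per_mirna > self.n_genes:
            raise SpecError("too many target genes for n_genes")
        if self.planted_mirnas > 0:
            if min(self.bridge_module_sizes) < 2:
                raise SpecError("bridge modules need at least 2 genes each")
            if (sum(self.bridge_module_sizes)
                    > self.planted_mirnas * self.targets_per_mirna):
                raise SpecError("bridge modules exceed available true target genes")
        if not 0 <= self.decoy_pair_fraction:
            raise SpecError("decoy_pair_fraction must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a synthetic cohort."""

    planted_mirnas: dict[str, float]            # miRNA id -> signed Delta
    true_pairs: list[tuple[str, str]]           # (mirna_id, gene_id)
    bridge: tuple[str, str] | None              # the high-betweenness interaction
    module_membership: dict[str, int]           # interaction-graph gene -> module id
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["true_pairs"] = [list(p) for p in self.true_pairs]
        d["bridge"] = list(self.bridge) if self.bridge else None
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["true_pairs"] = [tuple(p) for p in d["true_pairs"]]
        d["bridge"] = tuple(d["bridge"]) if d["bridge"] else None
        d["module_membership"] = {k: int(v) for k, v in d["module_membership"].items()}
        return cls(**d)


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(spec: SyntheticSpec):
    """Generate (miRNA matrix, mRNA matrix, annotations, ground truth).

    Background features are ``baseline + N(0, sigma_e)`` identically in both
    groups. Planted miRNA *i* receives a mean shift of ``+delta`` (even
    index) or ``-delta`` (odd index) in responders. Each true target gene is
    ``baseline_g - beta * (miRNA value - cohort mean) + N(0, sigma_e)``,
    which yields negative sample-level Pearson correlation and the opposite
    group-level fold change.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_responders, spec.n_nonresponders
    n = n1 + n2
    samples = _ids("S", n)
    groups = ["responder"] * n1 + ["non_responder"] * n2
    mirna_ids = _ids("miR-", spec.n_mirnas)
    gene_ids = _ids("GENE", spec.n_genes)

    # signed effects: alternate up/down across planted miRNAs
    planted = {
        mirna_ids[i]: spec.delta * (1 if i % 2 == 0 else -1)
        for i in range(spec.planted_mirnas)
    }

    # Baseline abundance is a property of the feature, not of the cohort:
    # a fixed RNG ties each feature id to one log2 baseline so independent
    # cohorts (different seeds) remain comparable, as real profiling runs are.
    base_rng = np.random.default_rng(615489302)
    mirna_base = base_rng.normal(8.0, 1.5, size=spec.n_mirnas)
    gene_base = base_rng.normal(8.0, 1.5, size=spec.n_genes)

    mirna_vals = (mirna_base[:, None]
                  + rng.normal(0.0, spec.sigma_e, size=(spec.n_mirnas, n)))
    resp = np.array([g == "responder" for g in groups])
    for i in range(spec.planted_mirnas):
        mirna_vals[i, resp] += planted[mirna_ids[i]]

    gene_vals = (gene_base[:, None]
                 + rng.normal(0.0, spec.sigma_e, size=(spec.n_genes, n)))
    true_pairs: list[tuple[str, str]] = []
    g_cursor = 0
    for i in range(spec.planted_mirnas):
        m_centered = mirna_vals[i] - mirna_vals[i].mean()
        for _ in range(spec.targets_per_mirna):
            gene_vals[g_cursor] = (gene_base[g_cursor]
                                   - spec.beta * m_centered
                                   + rng.normal(0.0, spec.sigma_e, size=n))
            true_pairs.append((mirna_ids[i], gene_ids[g_cursor]))
            g_cursor += 1

    mirna_mat = ExpressionMatrix(
        pd.DataFrame(mirna_vals, index=mirna_ids, columns=samples),
        feature_kind="miRNA")
    mrna_mat = ExpressionMatrix(
        pd.DataFrame(gene_vals, index=gene_ids, columns=samples),
        feature_kind="mRNA")
    annotations = [SampleAnnotation(s, g) for s, g in zip(samples, groups)]

    bridge, membership = _bridge_and_modules(spec, true_pairs)
    truth = GroundTruth(
        planted_mirnas=planted,
        true_pairs=true_pairs,
        bridge=bridge,
        module_membership=membership,
        seed=spec.seed,
    )
    return mirna_mat, mrna_mat, annotations, truth


def _bridge_and_modules(spec: SyntheticSpec, true_pairs):
    """Assign true target genes to the two interaction-graph modules.

    Genes are taken round-robin across the planted miRNAs so every planted
    miRNA owns at least one gene in the module union; the bridge connects the
    first gene of each module.
    """
    if not true_pairs:
        return None, {}
    by_mirna: dict[str, list[str]] = {}
    for m, g in true_pairs:
        by_mirna.setdefault(m, []).append(g)
    interleaved = [g for tier in itertools.zip_longest(*by_mirna.values())
                   for g in tier if g is not None]
    s1, s2 = spec.bridge_module_sizes
    module1 = interleaved[:s1]
    module2 = interleaved[s1:s1 + s2]
    membership = {g: 1 for g in module1}
    membership.update({g: 2 for g in module2})
    bridge = (module1[0], module2[0])
    return bridge, membership


def generate_pair_tables(truth: GroundTruth, spec: SyntheticSpec):
    """Emit two prediction tables whose intersection is exactly the true pairs.

    Every true pair appears in both tables; decoy pairs (never true targets)
    appear in exactly one table, alternating, so the source-intersection step
    removes all of them. Decoy count = floor(fraction x true pairs).
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_decoys = int(spec.decoy_pair_fraction * len(truth.true_pairs))
    mirna_ids = _ids("miR-", spec.n_mirnas)
    gene_ids = _ids("GENE", spec.n_genes)
    true_set = set(truth.true_pairs)
    decoys: list[tuple[str, str]] = []
    seen = set(true_set)
    while len(decoys) < n_decoys:
        m = mirna_ids[rng.integers(spec.n_mirnas)]
        g = gene_ids[rng.integers(spec.n_genes)]
        if (m, g) not in seen:
            decoys.append((m, g))
            seen.add((m, g))

    rows_a = list(truth.true_pairs) + decoys[0::2]
    rows_b = list(truth.true_pairs) + decoys[1::2]
    table_a = TargetPairTable(pd.DataFrame(
        [(m, g, "A") for m, g in rows_a],
        columns=["mirna_id", "gene_id", "source"]))
    table_b = TargetPairTable(pd.DataFrame(
        [(m, g, "B") for m, g in rows_b],
        columns=["mirna_id", "gene_id", "source"]))
    return table_a, table_b


def generate_interaction_graph(truth: GroundTruth,
                               spec: SyntheticSpec) -> InteractionTable:
    """Emit a gene-gene interaction table with planted community structure.

    Two cliques over the designated module genes are joined by one bridge
    edge; within-community and bridge scores are drawn above the global
    median, filler/background edges (between non-target background genes)
    below it. The table always carries at least as many low-score edges as
    high-score ones so the global median sits strictly between the two score
    bands and a strict >-median filter keeps exactly the community + bridge
    edges. In the filtered graph the bridge carries every cross-module
    shortest path and is therefore the unique top edge-betweenness edge.
    """
    rng = np.random.default_rng(spec.seed + 2)
    if not truth.module_membership:
        raise SpecError("no planted target genes: interaction graph undefined")
    modules: dict[int, list[str]] = {1: [], 2: []}
    for g, m in truth.module_membership.items():
        modules[m].append(g)
    if len(modules[1]) + len(modules[2]) > spec.n_genes:
        raise SpecError("module sizes exceed n_genes")

    high_rows: list[tuple[str, str, float]] = []
    for genes in modules.values():
        for a, b in itertools.combinations(genes, 2):
            high_rows.append((a, b, float(rng.uniform(0.60, 0.95))))
    high_rows.append((truth.bridge[0], truth.bridge[1],
                      float(rng.uniform(0.60, 0.95))))

    # low-score filler among background (non-target) genes; at least as many
    # rows as the high band so the global median separates the bands
    gene_ids = _ids("GENE", spec.n_genes)
    target_genes = {g for _, g in truth.true_pairs}
    background = [g for g in gene_ids if g not in target_genes]
    n_low = max(spec.background_edges, len(high_rows))
    low_rows: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()
    if len(background) < 2:
        raise SpecError("not enough background genes for filler interactions")
    max_pairs = len(background) * (len(background) - 1) // 2
    n_low = min(n_low, max_pairs)
    while len(low_rows) < n_low:
        a, b = (background[i] for i in rng.choice(len(background), 2, replace=False))
        key = (a, b) if a < b else (b, a)
        if key not in seen:
            seen.add(key)
            low_rows.append((key[0], key[1], float(rng.uniform(0.10, 0.40))))

    df = pd.DataFrame(high_rows + low_rows,
                      columns=["gene_a", "gene_b", "combined_score"])
    return InteractionTable(df)


def generate_all(spec: SyntheticSpec):
    """Convenience: cohort + pair tables + interaction table + truth."""
    mirna, mrna, ann, truth = generate_cohort(spec)
    table_a, table_b = generate_pair_tables(truth, spec)
    interactions = generate_interaction_graph(truth, spec)
    return mirna, mrna, ann, table_a, table_b, interactions, truth


def demo_cohort(seed: int = 2024):
    """The tiny fixed worked-example cohort: 12 samples, 8 miRNAs, 12 genes."""
    spec = SyntheticSpec(n_mirnas=8, n_genes=12, planted_mirnas=2,
                         targets_per_mirna=3, bridge_module_sizes=(3, 3),
                         background_edges=12, seed=seed)
    return spec, generate_all(spec)
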