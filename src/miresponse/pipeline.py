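"""End-to-end pipeline runner with a file manifest.

Each stage's output is written as a plain file (TSV / GraphML / JSON) under
the run directory; ``manifest.json`` records the config snapshot, input
digests, per-stage outputs, the seed and timestamps. A stage failure aborts
with the stage name while completed-stage outputs are kept on disk, so a
rerun can resume from inspection of the manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io as mio
from .diffexpr import results_frame
from .model import ResponseBiomarkerModel, StageError
from .simulate import SyntheticSpec, generate_all


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]           # name -> sha256 digest
    outputs: dict[str, list[str]] = field(default_factory=dict)  # stage -> paths
    seed: int = 0
    started: str = ""
    finished: str = ""

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def run_pipeline(config: mio.RunConfig, inputs: dict[str, str | Path],
                 out_dir: str | Path) -> RunManifest:
    """Run the full discovery flow from input files.

    ``inputs`` must name: mirna, mrna, annotations, pairs_a, pairs_b,
    interactions (paths); optionally gene_sets (GMT).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        inputs={k: mio.file_digest(v) for k, v in inputs.items()},
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    mirna = mio.read_expression(inputs["mirna"], feature_kind="miRNA")
    mrna = mio.read_expression(inputs["mrna"], feature_kind="mRNA")
    annotations = mio.read_annotations(inputs["annotations"])
    pairs_a = mio.read_target_pairs(inputs["pairs_a"], source="A")
    pairs_b = mio.read_target_pairs(inputs["pairs_b"], source="B")
    interactions = mio.read_interactions(inputs["interactions"])
    gene_sets = None
    if "gene_sets" in inputs:
        from .topology import read_gmt
        gene_sets = read_gmt(inputs["gene_sets"])

    model = ResponseBiomarkerModel(mirna, mrna, annotations, pairs_a,
                                   pairs_b, interactions, config=config,
                                   gene_sets=gene_sets)
    try:
        res = model.fit()
    except StageError:
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.save(out / "manifest.json")
        raise

    def emit(stage: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest.outputs.setdefault(stage, []).append(str(path))

    emit("differential_expression", "de_mirna.tsv",
         lambda p: results_frame(res.de_mirnas_all).to_csv(p, sep="\t", index=False))
    emit("differential_expression", "de_mrna.tsv",
         lambda p: results_frame(res.de_genes_all).to_csv(p, sep="\t", index=False))
    emit("coexpression_network", "coexpression_edges.tsv",
         lambda p: res.coexpression.edge_frame().to_csv(p, sep="\t", index=False))
    emit("coexpression_network", "coexpression.graphml",
         lambda p: mio.write_network(res.coexpression.graph, p, fmt="graphml"))
    emit("interaction_topology", "topology.tsv",
         lambda p: res.topology.nodes.to_csv(p, sep="\t"))
    emit("interaction_topology", "edge_betweenness.tsv",
         lambda p: Path(p).write_text(
             "gene_a\tgene_b\tedge_betweenness\n" + "".join(
                 f"{a}\t{b}\t{s:.10g}\n" for (a, b), s in res.topology.edges)))
    emit("interaction_topology", "modules.tsv",
         lambda p: Path(p).write_text(
             "gene_id\tmodule\n" + "".join(
                 f"{g}\t{m}\n" for g, m in sorted(res.partition.membership.items()))))
    if res.enrichment is not None:
        emit("interaction_topology", "enrichment.tsv",
             lambda p: res.enrichment.to_csv(p, sep="\t", index=False))
    emit("biomarker_selection", "panel.tsv",
         lambda p: res.panel.to_frame().to_csv(p, sep="\t", index=False))
    emit("biomarker_selection", "panel_provenance.json",
         lambda p: res.panel.to_json(p))
    emit("response_classifier", "cv_report.tsv",
         lambda p: res.cv_report.repeats.to_csv(p, sep="\t"))
    emit("response_classifier", "summary.txt",
         lambda p: Path(p).write_text(res.summary() + "\n"))

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(out / "manifest.json")
    return manifest


def write_synthetic_inputs(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a synthetic cohort and write it in the pipeline input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mirna, mrna, ann, ta, tb, inter, truth = generate_all(spec)
    paths = {
        "mirna": out / "mirna.tsv",
        "mrna": out / "mrna.tsv",
        "annotations": out / "annotations.tsv",
        "pairs_a": out / "targets_a.tsv",
        "pairs_b": out / "targets_b.tsv",
        "interactions": out / "interactions.tsv",
    }
    mio.write_expression(mirna, paths["mirna"])
    mio.write_expression(mrna, paths["mrna"])
    mio.write_annotations(ann, paths["annotations"])
    mio.write_target_pairs(ta, paths["pairs_a"])
    mio.write_target_pairs(tb, paths["pairs_b"])
    mio.write_interactions(inter, paths["interactions"])
    truth.to_json(out / "ground_truth.json")
    return paths


def run_demo(seed: int, out_dir: str | Path) -> RunManifest:
    """One-command synthetic demo: simulate at the study conditions, then run."""
    out = Path(out_dir)
    spec = SyntheticSpec(seed=seed)
    inputs = write_synthetic_inputs(spec, out / "inputs")
    config = mio.RunConfig(seed=seed)
    return run_pipeline(config, inputs, out / "results")
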