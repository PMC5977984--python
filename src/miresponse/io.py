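"""Readers, writers and run configuration.

All tabular formats are plain TSV with a header row (UTF-8). Expression
matrices may also be read from the GEO series-matrix text dialect, in which
the numeric table is delimited by ``!series_matrix_table_begin`` /
``!series_matrix_table_end`` sentinels and identifiers may be quoted.
Networks are written as GraphML (attributes preserved) or SIF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A log2 feature-by-sample expression matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Features in rows (index), samples in columns. Values are log2
        intensities and must be finite floats.
    feature_kind : {"miRNA", "mRNA"}
    """

    data: pd.DataFrame
    feature_kind: str = "mRNA"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("miRNA", "mRNA"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise FormatError("empty expression matrix")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample IDs")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric values in expression matrix")
        if not np.all(np.isfinite(values)):
            raise FormatError("non-finite values in expression matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class SampleAnnotation:
    """Group membership and optional clinical covariates for one sample."""

    sample_id: str
    group: str  # "responder" | "non_responder"
    covariates: Mapping[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("responder", "non_responder"):
            raise ValueError(f"unknown group {self.group!r}")


def check_annotations(matrix: ExpressionMatrix,
                      annotations: Sequence[SampleAnnotation]) -> dict[str, str]:
    """Validate annotation/sample correspondence; return sample->group map."""
    mapping = {a.sample_id: a.group for a in annotations}
    if len(mapping) != len(annotations):
        raise ValueError("duplicate sample annotations")
    missing = [s for s in matrix.sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    groups = {mapping[s] for s in matrix.sample_ids}
    if groups != {"responder", "non_responder"}:
        raise ValueError("both responder and non_responder groups are required")
    return mapping


@dataclass
class TargetPairTable:
    """miRNA -> target-gene prediction pairs from one source program."""

    pairs: pd.DataFrame  # columns: mirna_id, gene_id, source

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id", "source"}
        if not required.issubset(self.pairs.columns):
            raise FormatError(f"target pair table needs columns {sorted(required)}")
        if self.pairs.duplicated(["mirna_id", "gene_id", "source"]).any():
            raise FormatError("duplicate (mirna, gene, source) rows")

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["mirna_id"], self.pairs["gene_id"]))


@dataclass
class InteractionTable:
    """Gene-gene interactions with a STRING-style combined confidence score.

    Duplicate unordered pairs are collapsed keeping the maximum score;
    self-interactions and negative scores are format errors.
    """

    interactions: pd.DataFrame  # columns: gene_a, gene_b, combined_score

    def __post_init__(self) -> None:
        required = {"gene_a", "gene_b", "combined_score"}
        if not required.issubset(self.interactions.columns):
            raise FormatError(f"interaction table needs columns {sorted(required)}")
        df = self.interactions
        if (df["combined_score"] < 0).any():
            raise FormatError("negative combined_score")
        if (df["gene_a"] == df["gene_b"]).any():
            raise FormatError("self-interaction row")
        key = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
        df = df.assign(_key=key)
        df = (df.sort_values("combined_score", ascending=False)
                .drop_duplicates("_key", keep="first")
                .sort_index())
        self.interactions = (
            df.assign(gene_a=df["_key"].str[0], gene_b=df["_key"].str[1])
              .drop(columns="_key")
              .reset_index(drop=True)
        )

    @property
    def scores(self) -> np.ndarray:
        return self.interactions["combined_score"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.interactions)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable thresholds and parameters of the pipeline.

    Round-trips losslessly through YAML/JSON (`to_dict`/`from_dict`).
    """

    # differential-expression screen
    log2fc_min: float = 0.5
    p_max: float = 0.05
    fdr_mode: str = "report"      # "report": q computed, not gating; "gate": q < q_max also required
    q_max: float = 0.05
    # co-expression anti-correlation rule
    corr_rule: str = "negative+p+direction"  # clauses: negative r, corr p, opposite DE direction
    corr_p_max: float = 0.05
    # Markov clustering
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_prune_min: float = 1e-5
    mcl_max_iter: int = 100
    mcl_tol: float = 1e-8
    # key-interaction / panel selection
    top_k_edges: int = 2
    # SVM
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    scale_mode: str = "zscore"    # "zscore" | "minmax" | "none"
    # cross-validation
    cv_k: int = 5
    cv_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log2fc_min <= 0 or not (0 < self.p_max <= 1):
            raise ValueError("log2fc_min must be > 0 and p_max in (0, 1]")
        if self.mcl_inflation <= 1 or self.mcl_expansion < 2:
            raise ValueError("MCL requires inflation > 1 and expansion >= 2")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if isinstance(self.svm_gamma, (int, float)) and self.svm_gamma <= 0:
            raise ValueError("svm_gamma must be positive")
        if self.cv_k < 2 or self.cv_repeats < 1:
            raise ValueError("cv_k >= 2 and cv_repeats >= 1 required")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        return cls(**dict(d))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------

_GEO_BEGIN = "!series_matrix_table_begin"
_GEO_END = "!series_matrix_table_end"


def _strict_float_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a string frame to floats; any unparsable cell is a FormatError."""
    def conv(x: object) -> float:
        if x is None or (isinstance(x, float) and np.isnan(x)):
            raise FormatError("missing value in expression table")
        try:
            return float(x)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric cell {x!r}") from exc

    return df.map(conv).astype(float)


def read_expression(path: str | Path, dialect: str = "tsv",
                    feature_kind: str = "mRNA") -> ExpressionMatrix:
    """Read a feature x sample log2 expression matrix.

    ``dialect='tsv'`` expects the first column to hold feature IDs and the
    header row sample IDs. ``dialect='geo_series_matrix'`` extracts the table
    between the series-matrix sentinels and unquotes identifiers. Non-numeric
    cells (including ``NA``) raise :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "geo_series_matrix":
        lines = text.splitlines()
        try:
            lo = next(i for i, l in enumerate(lines) if l.strip() == _GEO_BEGIN)
            hi = next(i for i, l in enumerate(lines) if l.strip() == _GEO_END)
        except StopIteration:
            raise FormatError("series-matrix sentinels not found")
        text = "\n".join(l.replace('"', "") for l in lines[lo + 1:hi])
    elif dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    rows = [line.split("\t") for line in text.splitlines() if line != ""]
    if len(rows) < 2:
        raise FormatError("empty expression matrix")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError("ragged rows in expression table")
    header = rows[0][1:]
    index = [r[0] for r in rows[1:]]
    body = pd.DataFrame([r[1:] for r in rows[1:]], index=index, columns=header)
    return ExpressionMatrix(_strict_float_frame(body), feature_kind=feature_kind)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample annotation TSV (columns: sample_id, group, covariates...)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "group"}.issubset(df.columns):
        raise FormatError("annotation table needs sample_id and group columns")
    extra = [c for c in df.columns if c not in ("sample_id", "group")]
    return [
        SampleAnnotation(row["sample_id"], row["group"],
                         {c: row[c] for c in extra})
        for _, row in df.iterrows()
    ]


def write_annotations(annotations: Sequence[SampleAnnotation],
                      path: str | Path) -> None:
    covar_names = sorted({k for a in annotations for k in a.covariates})
    rows = [
        {"sample_id": a.sample_id, "group": a.group,
         **{c: a.covariates.get(c, "") for c in covar_names}}
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pair / interaction table I/O
# ---------------------------------------------------------------------------

def read_target_pairs(path: str | Path, source: str) -> TargetPairTable:
    """Read a miRNA->gene prediction TSV (columns mirna_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "gene_id"}.issubset(df.columns):
        raise FormatError("target pair table needs mirna_id and gene_id columns")
    df = df[["mirna_id", "gene_id"]].drop_duplicates()
    return TargetPairTable(df.assign(source=source).reset_index(drop=True))


def write_target_pairs(table: TargetPairTable, path: str | Path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a STRING-style interaction TSV (gene_a, gene_b, combined_score)."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"gene_a": str, "gene_b": str})
    if not {"gene_a", "gene_b", "combined_score"}.issubset(df.columns):
        raise FormatError(
            "interaction table needs gene_a, gene_b, combined_score columns")
    df["combined_score"] = pd.to_numeric(df["combined_score"], errors="raise")
    return InteractionTable(df[["gene_a", "gene_b", "combined_score"]])


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    table.interactions.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

def write_network(network: nx.Graph, path: str | Path,
                  fmt: str = "graphml", relation: str = "pp") -> None:
    """Write a graph as GraphML (attributes preserved) or SIF (one edge/line)."""
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in network.edges():
                fh.write(f"{u}\t{relation}\t{v}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
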