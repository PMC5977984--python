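"""Topology of the miRNA-mediated gene signal-transduction network.

The gene network keeps interactions whose combined score strictly exceeds
the median of *all* scores in the input table and whose endpoints are both
differentially expressed. Four per-node features are computed: degree,
relative betweenness centrality ``C'B(v) = [2/(n^2-3n+2)] * sum
sigma_st(v)/sigma_st`` (the Brandes normalization for undirected graphs),
closeness ``C(i) = 1 / sum_y d(y, i)`` (farness summed over the node's
component; an isolated node gets 0), and module membership from Markov
clustering. Hub genes exceed the median of degree, betweenness and
closeness simultaneously (all strict). Edge betweenness (unnormalized
shortest-path fractions summed over unordered pairs) ranks key
interactions. Module enrichment is a one-sided hypergeometric tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .diffexpr import DEResult, bh_fdr
from .io import InteractionTable


def filter_by_median_score(interactions: InteractionTable,
                           de_genes: list[str] | set[str]) -> nx.Graph:
    """Median-threshold the interaction table and restrict to DE genes.

    The median is taken over all combined scores in the table (before the
    DE restriction); an edge survives iff its score is strictly greater
    than the median and both endpoints are differentially expressed.
    Surviving edges define the node set (no isolated nodes).
    """
    if len(interactions) == 0:
        raise ValueError("interaction table is empty")
    de = set(de_genes)
    median = float(np.median(interactions.scores))
    g = nx.Graph()
    for row in interactions.interactions.itertuples(index=False):
        if (row.combined_score > median
                and row.gene_a in de and row.gene_b in de):
            g.add_edge(row.gene_a, row.gene_b,
                       combined_score=float(row.combined_score))
    if g.number_of_nodes() == 0:
        warnings.warn("median-score filter produced an empty network")
    return g


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Relative betweenness centrality C'B(v), in [0, 1] for connected graphs.

    Computed by Brandes' BFS accumulation; the normalization
    2/((n-1)(n-2)) equals the 2/(n^2-3n+2) prefactor. Pairs in different
    components contribute zero.
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("betweenness prefactor requires at least 3 nodes")
    return {v: float(c)
            for v, c in nx.betweenness_centrality(graph, normalized=True).items()}


def closeness(graph: nx.Graph) -> dict[str, float]:
    """Closeness C(i) = 1 / (sum of distances from i within its component)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    out: dict[str, float] = {}
    for v in graph.nodes():
        dists = nx.single_source_shortest_path_length(graph, v)
        farness = sum(dists.values())  # d(v, v) = 0
        out[v] = 1.0 / farness if farness > 0 else 0.0
    return out


def edge_betweenness(graph: nx.Graph) -> list[tuple[tuple[str, str], float]]:
    """Per-edge betweenness (unnormalized), ranked descending.

    Each unordered node pair (s, t) contributes the fraction of s-t shortest
    paths that traverse the edge. Ties keep their relative order by edge id.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    eb = nx.edge_betweenness_centrality(graph, normalized=False)
    return sorted(((tuple(sorted(e)), float(s)) for e, s in eb.items()),
                  key=lambda kv: (-kv[1], kv[0]))


@dataclass
class TopologyReport:
    """Per-node features with medians and hub flags; per-edge betweenness."""

    nodes: pd.DataFrame       # index gene; columns degree, betweenness, closeness, hub
    medians: dict[str, float]
    edges: list[tuple[tuple[str, str], float]]

    def hub_genes(self) -> list[str]:
        return select_hubs(self)


def topology_report(graph: nx.Graph) -> TopologyReport:
    """Degree / betweenness / closeness per node, medians, hub calls, edges."""
    if graph.number_of_nodes() < 3:
        raise ValueError("topology report requires at least 3 nodes")
    deg = dict(graph.degree())
    btw = betweenness(graph)
    clo = closeness(graph)
    nodes = sorted(graph.nodes())
    df = pd.DataFrame({
        "degree": [deg[v] for v in nodes],
        "betweenness": [btw[v] for v in nodes],
        "closeness": [clo[v] for v in nodes],
    }, index=pd.Index(nodes, name="gene_id"))
    medians = {c: float(df[c].median()) for c in df.columns}
    df["hub"] = ((df["degree"] > medians["degree"])
                 & (df["betweenness"] > medians["betweenness"])
                 & (df["closeness"] > medians["closeness"]))
    return TopologyReport(nodes=df, medians=medians, edges=edge_betweenness(graph))


def select_hubs(report: TopologyReport) -> list[str]:
    """Genes strictly above the median on all three features, by degree desc."""
    hubs = report.nodes[report.nodes["hub"]]
    return sorted(hubs.index, key=lambda g: (-report.nodes.loc[g, "degree"], g))


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """Node -> module assignment from Markov clustering."""

    membership: dict[str, int]
    iterations: int
    converged: bool

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.membership.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def modules(self) -> dict[int, list[str]]:
        mods: dict[int, list[str]] = {}
        for v, m in sorted(self.membership.items()):
            mods.setdefault(m, []).append(v)
        return mods


def mcl(graph: nx.Graph, inflation: float = 2.0, expansion: int = 2,
        prune_min: float = 1e-5, max_iter: int = 100,
        tol: float = 1e-8) -> ModulePartition:
    """Markov clustering on an unweighted graph with unit self-loops.

    Simulates flow: the column-stochastic transition matrix is alternately
    raised to the ``expansion`` power (spreading flow) and inflated
    (elementwise power ``inflation`` then column renormalization,
    sharpening flow), with entries below ``prune_min`` zeroed, until the
    matrix change drops below ``tol``. Modules are read from the limit
    matrix: attractor rows (positive diagonal) span clusters; overlapping
    attractor systems are merged; a node attracted to several clusters goes
    to the one holding more of its column mass (ties to the smaller module
    id). Deterministic for fixed parameters.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if inflation <= 1 or expansion < 2:
        raise ValueError("inflation > 1 and expansion >= 2 required")
    nodes = sorted(graph.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m = np.eye(n)
    for u, v in graph.edges():
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = 1.0
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        m[m < prune_min] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge in {max_iter} iterations")

    # interpret: attractors have positive diagonal; each attractor row's
    # support is one cluster; merge overlapping attractor systems
    eps = 1e-9
    attractors = [i for i in range(n) if m[i, i] > eps]
    clusters: list[set[int]] = []
    for i in attractors:
        support = set(np.nonzero(m[i] > eps)[0]) | {i}
        merged = False
        for c in clusters:
            if c & support:
                c |= support
                merged = True
                break
        if merged:  # merging may chain-connect earlier clusters
            changed = True
            while changed:
                changed = False
                for a in range(len(clusters)):
                    for b in range(a + 1, len(clusters)):
                        if clusters[a] & clusters[b]:
                            clusters[a] |= clusters.pop(b)
                            changed = True
                            break
                    if changed:
                        break
        else:
            clusters.append(support)

    membership: dict[str, int] = {}
    clusters.sort(key=lambda c: min(c))
    assigned: dict[int, int] = {}
    for mod_id, c in enumerate(clusters, start=1):
        for i in c:
            if i in assigned:
                # node claimed by two attractor systems: larger column mass wins
                prev_mod = assigned[i]
                prev_mass = sum(m[j, i] for j in clusters[prev_mod - 1])
                this_mass = sum(m[j, i] for j in c)
                if this_mass > prev_mass:
                    assigned[i] = mod_id
            else:
                assigned[i] = mod_id
    # any node with no attractor support joins the module holding most of its column
    next_id = len(clusters) + 1
    for i in range(n):
        if i not in assigned:
            masses = [(sum(m[j, i] for j in c), -mod_id)
                      for mod_id, c in enumerate(clusters, start=1)]
            if masses and max(masses)[0] > eps:
                assigned[i] = -max(masses)[1]
            else:
                assigned[i] = next_id
                next_id += 1
    for v, i in idx.items():
        membership[v] = assigned[i]
    # renumber modules consecutively by smallest member node
    order = sorted(set(membership.values()),
                   key=lambda mod: min(v for v, mm in membership.items() if mm == mod))
    remap = {old: new for new, old in enumerate(order, start=1)}
    membership = {v: remap[mm] for v, mm in membership.items()}
    return ModulePartition(membership=membership, iterations=it,
                           converged=converged)


# ---------------------------------------------------------------------------
# module enrichment
# ---------------------------------------------------------------------------

def enrich_modules(partition: ModulePartition,
                   gene_sets: dict[str, set[str]],
                   universe: set[str]) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each module in each gene set.

    For a module of size m, a set of size K (within the universe of size N)
    and overlap k, the p-value is P(X >= k) for X hypergeometric(N, K, m).
    BH correction is applied across all (module, set) pairs.
    """
    modules = partition.modules()
    if not set().union(*modules.values()) <= universe:
        raise ValueError("universe must contain all module genes")
    n_univ = len(universe)
    rows = []
    for mod_id, genes in modules.items():
        mod_genes = set(genes)
        for set_name, members in gene_sets.items():
            in_univ = members & universe
            if not in_univ:
                warnings.warn(f"gene set {set_name!r} disjoint from universe; skipped")
                continue
            k = len(mod_genes & in_univ)
            p = float(scipy.stats.hypergeom.sf(k - 1, n_univ, len(in_univ),
                                               len(mod_genes)))
            rows.append({"module": mod_id, "gene_set": set_name,
                         "module_size": len(mod_genes), "set_size": len(in_univ),
                         "overlap": k, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["module", "gene_set", "module_size",
                                     "set_size", "overlap", "p_value"])
    if len(df):
        df["fdr_q"] = bh_fdr(df["p_value"].to_numpy())
    else:
        df["fdr_q"] = pd.Series(dtype=float)
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file (name, description, genes... per line)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets
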