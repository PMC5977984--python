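"""Differential expression screening for small two-group cohorts.

The screen uses a random-variance-model (RVM) moderated t-test: per-feature
variances are shrunk toward an inverse-gamma prior fitted across all
features, which adds 2a effective degrees of freedom — a substantial gain
when each group has only ~6 samples. Under the model the pooled sample
variance satisfies ``s^2 * a * b ~ F(d, 2a)`` with d residual degrees of
freedom, the moderated variance is ``(d s^2 + 2/b) / (d + 2a)`` and the
moderated statistic is referred to a t distribution with ``d + 2a`` df.

Significance is gated on ``|log2FC| > log2fc_min`` (strict) and
``p < p_max`` (strict); BH-FDR q-values are computed and reported, with an
optional q-value gate in the run configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize
import scipy.spatial.distance as ssd
import scipy.stats

from .io import ExpressionMatrix, SampleAnnotation, check_annotations

_A_CAP = 1e6  # a -> infinity guard for the prior shape


class FitError(RuntimeError):
    """Raised when the variance-prior fit is degenerate or fails to converge."""


@dataclass(frozen=True)
class RVMPrior:
    """Fitted inverse-gamma variance prior (F-distribution parameterization)."""

    a: float
    b: float
    loglik: float
    n_features: int

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("prior parameters must be positive")


@dataclass
class DEResult:
    """Per-feature differential-expression statistics."""

    feature_id: str
    mean_responder: float
    mean_nonresponder: float
    log2fc: float               # responder - non_responder, log2 units
    t_stat: float
    df_effective: float
    p_value: float
    fdr_q: float = np.nan
    significant: bool = False

    @property
    def fold_change(self) -> float:
        return float(2.0 ** self.log2fc)

    @property
    def direction(self) -> str:
        return "up" if self.log2fc >= 0 else "down"


def pooled_variances(matrix: ExpressionMatrix,
                     annotations: Sequence[SampleAnnotation]):
    """Per-feature pooled within-group variances and residual df."""
    mapping = check_annotations(matrix, annotations)
    groups = np.array([mapping[s] for s in matrix.sample_ids])
    x1 = matrix.values[:, groups == "responder"]
    x2 = matrix.values[:, groups == "non_responder"]
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * x1.var(axis=1, ddof=1)
          + (n2 - 1) * x2.var(axis=1, ddof=1)) / d
    return s2, d, x1, x2


def fit_rvm_prior(sample_variances: np.ndarray, df: int) -> RVMPrior:
    """Maximum-likelihood fit of the (a, b) variance prior.

    The model: ``s^2 * a * b ~ F(df, 2a)``. The likelihood is maximized over
    (log a, log b) by Nelder-Mead from a fixed start, so the fit is
    deterministic and invariant to feature order. Exactly constant observed
    variances (zero spread) are degenerate for this family and raise
    :class:`FitError`; near-degenerate data are handled by capping ``a``.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if len(s2) < 20:
        raise FitError("need at least 20 features with finite variance")
    if np.any(s2 < 0) or np.all(s2 <= 0):
        raise FitError("invalid variances")
    s2 = s2[s2 > 0]
    if df < 1:
        raise FitError("residual df must be >= 1")
    spread = s2.max() / s2.min() - 1.0
    if spread < 1e-10:
        raise FitError("constant variances: variance prior is degenerate (a -> inf)")

    def nll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        if a > _A_CAP:
            return np.inf
        # density of s^2 when s^2 * a * b ~ F(df, 2a)
        ll = scipy.stats.f.logpdf(s2 * a * b, df, 2 * a) + np.log(a * b)
        return -float(np.sum(ll))

    start = np.log([1.0, 1.0 / np.mean(s2)])
    res = scipy.optimize.minimize(nll, start, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-10,
                                           "maxiter": 5000})
    if not res.success and not np.isfinite(res.fun):
        raise FitError(f"variance prior fit failed: {res.message}")
    a, b = np.exp(res.x)
    if a >= _A_CAP * 0.99:
        warnings.warn("variance prior shape hit its cap; variances are nearly "
                      "homogeneous and the test degrades to a pooled z-test")
        a = _A_CAP
    return RVMPrior(a=float(a), b=float(b), loglik=-float(res.fun),
                    n_features=len(s2))


def rvm_t_test(matrix: ExpressionMatrix,
               annotations: Sequence[SampleAnnotation],
               prior: RVMPrior) -> list[DEResult]:
    """Moderated two-sample t-test for every feature.

    log2FC is responder minus non-responder. Two-sided p-values come from a
    t distribution with ``d + 2a`` degrees of freedom.
    """
    s2, d, x1, x2 = pooled_variances(matrix, annotations)
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    var_mod = (d * s2 + 2.0 / prior.b) / (d + 2.0 * prior.a)
    df_eff = d + 2.0 * prior.a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(var_mod * (1.0 / n1 + 1.0 / n2))
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df_eff)
    return [
        DEResult(feature_id=fid, mean_responder=float(m1[i]),
                 mean_nonresponder=float(m2[i]), log2fc=float(m1[i] - m2[i]),
                 t_stat=float(t[i]), df_effective=float(df_eff),
                 p_value=float(min(p[i], 1.0)))
        for i, fid in enumerate(matrix.feature_ids)
    ]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return scipy.stats.false_discovery_control(p, method="bh")


def screen_de(results: list[DEResult], log2fc_min: float = 0.5,
              p_max: float = 0.05, q_max: float | None = None):
    """Attach q-values and significance flags; partition by direction.

    A feature is significant iff ``|log2fc| > log2fc_min`` and
    ``p < p_max`` (both strict), plus ``q < q_max`` if a q-gate is given.
    Both lists are ordered by descending |t|, then feature id.
    """
    if log2fc_min <= 0 or p_max <= 0:
        raise ValueError("thresholds must be positive")
    q = bh_fdr([r.p_value for r in results])
    for r, qi in zip(results, q):
        r.fdr_q = float(qi)
        r.significant = (abs(r.log2fc) > log2fc_min and r.p_value < p_max
                         and (q_max is None or r.fdr_q < q_max))
    key = lambda r: (-abs(r.t_stat), r.feature_id)
    up = sorted((r for r in results if r.significant and r.log2fc > 0), key=key)
    down = sorted((r for r in results if r.significant and r.log2fc < 0), key=key)
    return up, down


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    rows = [{
        "feature_id": r.feature_id, "mean_responder": r.mean_responder,
        "mean_nonresponder": r.mean_nonresponder, "log2fc": r.log2fc,
        "fold_change": r.fold_change, "t_stat": r.t_stat,
        "df_effective": r.df_effective, "p_value": r.p_value,
        "fdr_q": r.fdr_q, "direction": r.direction,
        "significant": r.significant,
    } for r in results]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge history: (i, j, height, new_node) per merge."""

    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]
    leaf_ids: list[str]

    def to_newick(self) -> str:
        n = len(self.leaf_ids)
        names: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for i, j, h, new in self.merges:
            bi, bj = h - heights[i], h - heights[j]
            names[new] = f"({names[i]}:{bi:g},{names[j]}:{bj:g})"
            heights[new] = h
        root = self.merges[-1][3] if self.merges else 0
        return names[root] + ";"


def hierarchical_cluster(matrix: ExpressionMatrix,
                         distance: str = "one_minus_pearson",
                         linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of features.

    Repeatedly merges the closest remaining pair, replacing it by a branch
    whose distance to the rest follows the linkage rule; branch length is
    the merge distance. ``one_minus_pearson`` uses 1 - Pearson correlation
    between feature profiles; a constant feature makes that distance
    undefined and raises.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    if linkage not in ("single", "average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    x = matrix.values
    if distance == "euclidean":
        dists = ssd.pdist(x, metric="euclidean")
    elif distance == "one_minus_pearson":
        if np.any(x.std(axis=1) == 0):
            raise ValueError("constant feature: correlation distance undefined")
        dists = ssd.pdist(x, metric="correlation")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    z = sch.linkage(dists, method=linkage)
    n = x.shape[0]
    merges = [(int(z[k, 0]), int(z[k, 1]), float(z[k, 2]), n + k)
              for k in range(z.shape[0])]
    return Dendrogram(merges=merges,
                      leaf_order=[int(i) for i in sch.leaves_list(z)],
                      leaf_ids=matrix.feature_ids)
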