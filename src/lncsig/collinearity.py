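"""Multicollinearity reduction by stability-assessed correlation clustering.

Highly correlated features distort interpretation of feature rankings:
related features compete for the same rank. Features are standardized,
hierarchically clustered under the inverse-absolute-correlation distance
``d = 1 - |r|`` with complete linkage, and clusters whose minimum
intra-cluster absolute correlation exceeds a threshold (default 0.8) are
collapsed onto a single proxy: the member with the highest univariate
AUPR against the class label. Cluster uncertainty is assessed by
bootstrap resampling of transcripts (with an optional multiscale
extrapolation to approximately-unbiased p-values); only stable clusters
(p < alpha) are collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from lncsig.features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationClustering",
    "standardize",
    "correlated_clusters",
    "choose_proxy",
    "reduce_table",
    "collapse_collinear",
]

_EPS = 1e-12


@dataclass
class CorrelationClustering:
    """Result of correlation clustering: dendrogram, stable clusters, proxies."""

    feature_names: list[str]
    linkage_matrix: np.ndarray | None
    clusters: list[frozenset[str]]
    support: dict[frozenset[str], float]
    pvalues: dict[frozenset[str], float]
    threshold: float
    proxies: dict[frozenset[str], str] = field(default_factory=dict)

    def report(self) -> dict:
        """JSON-serializable summary of clusters, stability, and proxy election."""
        return {
            "threshold": self.threshold,
            "clusters": [
                {
                    "members": sorted(c),
                    "support": self.support[c],
                    "p_value": self.pvalues[c],
                    "proxy": self.proxies.get(c),
                    "removed": sorted(set(c) - {self.proxies[c]})
                    if c in self.proxies
                    else None,
                }
                for c in self.clusters
            ],
        }


def standardize(table: FeatureTable, return_dropped: bool = False):
    """Center each feature at 0 and scale to unit sample standard deviation.

    Constant features carry no information and make correlations undefined;
    they are dropped and reported. Missing values are ignored in the moments
    and preserved in the output.
    """
    if table.n < 2:
        raise ValueError("standardization requires at least 2 rows")
    df = table.values
    sd = df.std(axis=0, ddof=1)
    constant = list(df.columns[(sd == 0) | sd.isna()])
    if constant:
        logger.info("dropping %d constant features: %s", len(constant), constant)
    kept = df.drop(columns=constant)
    out = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)
    result = FeatureTable(out, table.labels)
    return (result, constant) if return_dropped else result


def _abs_corr(values: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation matrix on pairwise-complete observations."""
    import pandas as pd

    r = pd.DataFrame(values).corr(method="pearson", min_periods=2).to_numpy()
    np.fill_diagonal(r, 1.0)
    r = np.nan_to_num(r, nan=0.0)
    return np.abs(np.clip(r, -1.0, 1.0))


def _cluster_once(values: np.ndarray, threshold: float):
    """Complete-linkage clusters whose members are all pairwise |r| > threshold."""
    p = values.shape[1]
    absr = _abs_corr(values)
    dist = 1.0 - absr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="complete")
    # complete-linkage node height == max pairwise distance inside the node,
    # so cutting at 1 - threshold gives maximal candidate nodes directly
    assign = fcluster(Z, t=1.0 - threshold - _EPS, criterion="distance")
    clusters = []
    for cid in np.unique(assign):
        members = np.flatnonzero(assign == cid)
        if len(members) < 2:
            continue
        sub = absr[np.ix_(members, members)]
        if sub[np.triu_indices(len(members), k=1)].min() > threshold:
            clusters.append(frozenset(members.tolist()))
    return Z, clusters


def _au_pvalue(scales: list[float], supports: list[float]) -> float:
    """Approximately-unbiased support via multiscale probit extrapolation.

    Fits 1 - support(r) = Phi(d*sqrt(r) + c/sqrt(r)) over relative sample
    sizes r and extrapolates to Phi(d - c), following the multiscale
    bootstrap scheme of pvclust-style cluster-uncertainty assessment.
    Returns the p-value 1 - AU.
    """
    eps = 1e-6
    z = norm.ppf(np.clip(1.0 - np.asarray(supports), eps, 1 - eps))
    sq = np.sqrt(np.asarray(scales))
    X = np.column_stack([sq, 1.0 / sq])
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    d, c = coef
    return float(norm.cdf(d - c))


def correlated_clusters(
    table: FeatureTable,
    threshold: float = 0.8,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    multiscale: bool = False,
) -> CorrelationClustering:
    """Find stable clusters of highly correlated features.

    A candidate cluster is a maximal complete-linkage dendrogram node whose
    members all satisfy pairwise ``|r| > threshold``. Its support is the
    fraction of ``n_boot`` row-resampled clusterings in which the identical
    member set reappears; with ``multiscale=True``, supports at several
    resample sizes are extrapolated to an approximately-unbiased p-value.
    Clusters with p-value < ``alpha`` are kept.
    """
    if table.n < 3:
        raise ValueError("need at least 3 rows to assess cluster stability")
    values = table.values.to_numpy()
    names = table.feature_names
    Z, candidates = _cluster_once(values, threshold)
    named = [frozenset(names[i] for i in c) for c in candidates]

    rng = np.random.default_rng(seed)
    n = values.shape[0]
    scales = [0.6, 0.8, 1.0, 1.2, 1.4] if multiscale else [1.0]
    counts = {c: {r: 0 for r in scales} for c in named}
    reps = {r: max(1, round(n_boot / len(scales))) for r in scales}
    for r in scales:
        size = max(3, int(round(r * n)))
        for _ in range(reps[r]):
            idx = rng.integers(0, n, size=size)
            _, boot_clusters = _cluster_once(values[idx], threshold)
            boot_named = {frozenset(names[i] for i in c) for c in boot_clusters}
            for c in named:
                if c in boot_named:
                    counts[c][r] += 1

    support: dict[frozenset, float] = {}
    pvalues: dict[frozenset, float] = {}
    for c in named:
        per_scale = {r: counts[c][r] / reps[r] for r in scales}
        support[c] = per_scale[1.0]
        if multiscale:
            pvalues[c] = _au_pvalue(scales, [per_scale[r] for r in scales])
        else:
            pvalues[c] = 1.0 - support[c]
    stable = [c for c in named if pvalues[c] < alpha]
    return CorrelationClustering(
        feature_names=names,
        linkage_matrix=Z,
        clusters=stable,
        support={c: support[c] for c in stable},
        pvalues={c: pvalues[c] for c in stable},
        threshold=threshold,
    )


def choose_proxy(cluster: frozenset[str] | set[str], table: FeatureTable) -> str:
    """Elect the cluster member with the highest univariate AUPR for the class.

    Ties break lexicographically. Requires class labels.
    """
    from lncsig.selection import univariate_aupr_table

    if not cluster:
        raise ValueError("empty cluster")
    if table.labels is None:
        raise ValueError("proxy election requires class labels")
    sub = table.select(sorted(cluster))
    scores = univariate_aupr_table(sub)
    best = scores.sort_values(["AUPR", "feature"], ascending=[False, True])
    return str(best.iloc[0]["feature"])


def reduce_table(table: FeatureTable, clustering: CorrelationClustering) -> FeatureTable:
    """Drop clustered non-proxy features; proxies must already be elected.

    Idempotent: reducing an already-reduced table changes nothing.
    """
    to_drop: set[str] = set()
    for cluster in clustering.clusters:
        proxy = clustering.proxies.get(cluster)
        if proxy is None:
            raise ValueError(f"no proxy elected for cluster {sorted(cluster)}")
        to_drop |= set(cluster) - {proxy}
    kept = [f for f in table.feature_names if f not in to_drop]
    return table.select(kept)


def collapse_collinear(
    table: FeatureTable,
    threshold: float = 0.8,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    multiscale: bool = False,
) -> tuple[FeatureTable, CorrelationClustering, list[str]]:
    """Full reduction pipeline: standardize, cluster, elect proxies, collapse.

    Returns the reduced (standardized) table, the clustering with proxies
    filled in, and the list of constant features dropped at standardization.
    """
    std, constant = standardize(table, return_dropped=True)
    clustering = correlated_clusters(
        std, threshold=threshold, n_boot=n_boot, alpha=alpha, seed=seed,
        multiscale=multiscale,
    )
    for cluster in clustering.clusters:
        clustering.proxies[cluster] = choose_proxy(cluster, std)
    return reduce_table(std, clustering), clustering, constant
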