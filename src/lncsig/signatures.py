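"""Signature stability and consensus grouping of top-k signatures.

A *signature* is the set of the k top-ranked features produced by one
selection algorithm. Feature-selection algorithms are sensitive to small
perturbations of the training data, so each signature's stability is
quantified as the mean overlap ``|S intersect S'_i| / k`` between the
full-data signature S and signatures S'_i recomputed on random 80%
subsamples. Signatures from stable algorithms are then clustered by
Jaccard distance with complete linkage; cutting the tree (default height
0.45) yields consensus signature groups, each reported with its feature
union/intersection and a per-category breakdown.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from lncsig.features import (
    DINUCLEOTIDES,
    TRINUCLEOTIDES,
    FeatureTable,
)
from lncsig.selection import (
    RankedFeatureList,
    aggregate_mean,
    aggregate_mode,
    rank_features,
    top_k,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "SignatureClustering",
    "stability",
    "ensemble_over_subsamples",
    "jaccard_distance",
    "cluster_signatures",
    "feature_category",
]

_BASIC = {"TxNex", "TxLen", "TxExLenAvg"}
_ORF = {"OrfLen", "OrfProp", "KOZAK"}
_KMERS = set(DINUCLEOTIDES) | set(TRINUCLEOTIDES)


@dataclass
class Signature:
    """A size-k ordered feature set with provenance and optional stability."""

    name: str
    features: list[str]
    source: str = ""
    stability: float | None = None

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("signature must contain at least one feature")
        if len(set(self.features)) != len(self.features):
            raise ValueError("signature contains duplicate features")

    @property
    def k(self) -> int:
        return len(self.features)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.features)


@dataclass
class SignatureClustering:
    """Complete-linkage grouping of signatures under Jaccard distance."""

    signatures: list[Signature]
    linkage_matrix: np.ndarray | None
    cut: float
    groups: list[dict] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def feature_category(name: str) -> str:
    """Assign a feature name to BASIC / ORF / CONS / NUCLEO / REPS."""
    if name in _BASIC:
        return "BASIC"
    if name in _ORF:
        return "ORF"
    if name == "FickScore" or name in _KMERS:
        return "NUCLEO"
    if "." in name:
        return "REPS"
    if name.endswith(("mx", "mn")) or name.endswith("m"):
        return "CONS"
    return "OTHER"


RankerFn = Callable[[FeatureTable, int], RankedFeatureList]


def _resolve_ranker(method: "str | RankerFn", params: dict | None) -> RankerFn:
    if callable(method):
        return method
    return lambda tbl, sd: rank_features(tbl, method, params=params, seed=sd)


def _stratified_subsample(
    y: np.ndarray, frac: float, rng: np.random.Generator, replace: bool
) -> np.ndarray:
    """Row indices of a subsample holding ceil(frac*n) rows, stratified by class.

    Stratification guarantees both classes survive the draw even at strong
    class skew; per-class sizes are proportional with at least one row each.
    """
    n = len(y)
    total = math.ceil(frac * n)
    classes = np.unique(y)
    sizes = {}
    for c in classes:
        sizes[c] = max(1, round(total * (y == c).sum() / n))
    picked = []
    for c in classes:
        members = np.flatnonzero(y == c)
        picked.append(rng.choice(members, size=sizes[c], replace=replace))
    return np.concatenate(picked)


def stability(
    table: FeatureTable,
    method: "str | RankerFn",
    k: int,
    n_rep: int = 100,
    frac: float = 0.8,
    seed: int = 0,
    params: dict | None = None,
) -> float:
    """Mean overlap between the full-data signature and subsampled signatures.

    S is the top-k on the full table; each of ``n_rep`` draws takes 80% of
    the rows without replacement (stratified by class), recomputes the
    top-k signature S'_i, and contributes ``|S intersect S'_i| / k``. Returns
    the average, a value in [0, 1] that equals 1 for a data-independent
    ranker and approaches k/p for rankings of pure noise.
    """
    if table.labels is None:
        raise ValueError("stability requires class labels")
    if k > table.p:
        raise ValueError(f"k={k} exceeds feature count {table.p}")
    ranker = _resolve_ranker(method, params)
    rng = np.random.default_rng(seed)
    full = set(top_k(ranker(table, seed), k).features)
    y = table.y
    overlaps = []
    for i in range(n_rep):
        idx = _stratified_subsample(y, frac, rng, replace=False)
        sub = table.subset_rows(idx)
        sub_sig = set(top_k(ranker(sub, seed + i + 1), k).features)
        overlaps.append(len(full & sub_sig) / k)
    return float(np.mean(overlaps))


def ensemble_over_subsamples(
    table: FeatureTable,
    method: "str | RankerFn",
    B: int,
    k: int | None = None,
    aggregation: str = "EFmn",
    frac: float = 0.8,
    seed: int = 0,
    params: dict | None = None,
) -> RankedFeatureList:
    """Aggregate one algorithm's rankings over B bootstrap-style subsamples.

    Each of the B draws takes 80% of the rows *with* replacement (stratified
    by class); the resulting rankings are merged with the named aggregation
    function. ``k`` is accepted for symmetry with :func:`stability` but the
    full aggregated ranking is returned, so any top-k can be taken from it.
    """
    if aggregation not in ("EFmn", "EFmd"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if table.labels is None:
        raise ValueError("subsample ensembles require class labels")
    ranker = _resolve_ranker(method, params)
    rng = np.random.default_rng(seed)
    y = table.y
    lists = []
    for b in range(B):
        idx = _stratified_subsample(y, frac, rng, replace=True)
        # deduplicate row ids for the table container; resampling weight is
        # carried by which rows survive the draw
        idx = np.unique(idx)
        lists.append(ranker(table.subset_rows(idx), seed + b + 1))
    agg = aggregate_mean(lists) if aggregation == "EFmn" else aggregate_mode(lists)
    ranked = agg.to_ranked_list()
    method_id = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    ranked.method = f"{method_id}+{aggregation}xB{B}"
    ranked.seed = seed
    return ranked


def jaccard_distance(a: "Signature | set | frozenset", b: "Signature | set | frozenset") -> float:
    """1 - |A intersect B| / |A union B| on the signatures' feature sets."""
    sa = a.as_set() if isinstance(a, Signature) else frozenset(a)
    sb = b.as_set() if isinstance(b, Signature) else frozenset(b)
    if not sa or not sb:
        raise ValueError("signatures must be non-empty")
    return 1.0 - len(sa & sb) / len(sa | sb)


def cluster_signatures(
    signatures: list[Signature],
    cut: float = 0.45,
    stability_floor: float = 0.7,
) -> SignatureClustering:
    """Group top-k signatures into consensus signatures.

    Signatures whose stability is known and below ``stability_floor`` are
    excluded first (unstable algorithms would only blur the consensus);
    the rest are clustered by complete linkage on pairwise Jaccard
    distances and the tree is cut at ``cut``. Each group reports its member
    algorithms, the union and intersection of their features, and a
    BASIC/ORF/CONS/NUCLEO/REPS breakdown of the union.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures to cluster")
    kept = [s for s in signatures if s.stability is None or s.stability >= stability_floor]
    excluded = [s.name for s in signatures if s not in kept]
    if excluded:
        logger.info("excluded unstable signatures: %s", excluded)
    if not kept:
        raise ValueError("all signatures fall below the stability floor")

    if len(kept) == 1:
        groups = [_group_record([kept[0]])]
        return SignatureClustering(kept, None, cut, groups, excluded)

    m = len(kept)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = jaccard_distance(kept[i], kept[j])
    Z = linkage(squareform(dist, checks=False), method="complete")
    assign = fcluster(Z, t=cut, criterion="distance")
    groups = []
    for cid in np.unique(assign):
        members = [kept[i] for i in np.flatnonzero(assign == cid)]
        groups.append(_group_record(members))
    groups.sort(key=lambda g: g["members"])
    return SignatureClustering(kept, Z, cut, groups, excluded)


def _group_record(members: list[Signature]) -> dict:
    union = sorted(set().union(*(m.as_set() for m in members)))
    inter = sorted(frozenset.intersection(*(m.as_set() for m in members)))
    by_cat: dict[str, list[str]] = {}
    for f in union:
        by_cat.setdefault(feature_category(f), []).append(f)
    return {
        "members": sorted(m.name for m in members),
        "sources": sorted(m.source for m in members),
        "features_union": union,
        "features_intersection": inter,
        "by_category": {c: sorted(fs) for c, fs in sorted(by_cat.items())},
    }
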