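"""Multivariate feature ranking: nine base algorithms and two rank ensembles.

Three algorithm families are covered, as is standard in feature-selection
comparisons:

* filter based — Wilcoxon rank-sum test (``WT``), Information Gain
  (``IG``), Gain Ratio (``GR``), ReliefF (``RFS``);
* wrapper based — Recursive Feature Elimination with a linear SVM
  (``RFE``) and Greedy Forward Selection with least squares (``GFS``);
* embedded — Lasso (``LR``), Elastic Net (``EN``), and Random Forest
  permutation importance (``RF``).

Rankings (1 = most relevant) from several algorithms or subsamples can
be aggregated with the mean of ranks (``EFmn``, equivalent to a Borda
count) or the mode of ranks (``EFmd``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE as _SklearnRFE
from sklearn.linear_model import enet_path, lasso_path
from sklearn.svm import SVC

from lncsig.evaluation import score_metrics
from lncsig.features import FeatureTable

__all__ = [
    "RankedFeatureList",
    "EnsembleScore",
    "BASE_METHODS",
    "ENSEMBLE_METHODS",
    "rank_features",
    "aggregate_mean",
    "aggregate_mode",
    "top_k",
    "univariate_aupr_table",
]

BASE_METHODS = ("WT", "IG", "GR", "RFS", "RFE", "GFS", "LR", "EN", "RF")
ENSEMBLE_METHODS = ("EFmn", "EFmd")


@dataclass
class RankedFeatureList:
    """One algorithm's ordering of the feature set (rank 1 = most relevant)."""

    method: str
    features: list[str]  # best first
    scores: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("ranking contains duplicate features")

    @property
    def ranks(self) -> dict[str, int]:
        return {f: i + 1 for i, f in enumerate(self.features)}


@dataclass
class EnsembleScore:
    """Aggregate rank score S_f per feature over B rankings."""

    method: str  # EFmn or EFmd
    scores: dict[str, float]
    B: int
    ordering: list[str] = field(default_factory=list)

    def to_ranked_list(self) -> RankedFeatureList:
        return RankedFeatureList(self.method, list(self.ordering), dict(self.scores))


def _check_labeled(table: FeatureTable) -> np.ndarray:
    if table.labels is None:
        raise ValueError("feature ranking requires class labels")
    y = table.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    return y


def _clean_values(table: FeatureTable) -> np.ndarray:
    """Feature matrix with per-column median imputation of missing values."""
    X = table.values.to_numpy(dtype=float).copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.isnan(col).any():
            med = np.nanmedian(col)
            col[np.isnan(col)] = med if np.isfinite(med) else 0.0
    return X


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _order_by_score(names: list[str], score: np.ndarray, descending: bool) -> list[str]:
    """Deterministic ordering: by score, ties broken lexicographically."""
    key = -score if descending else score
    idx = sorted(range(len(names)), key=lambda i: (key[i], names[i]))
    return [names[i] for i in idx]


def _wilcoxon_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    pvals = np.empty(X.shape[1])
    pos, neg = X[y == 1], X[y == 0]
    for j in range(X.shape[1]):
        if np.all(pos[:, j] == pos[0, j]) and np.all(neg[:, j] == neg[0, j]) and (
            pos[0, j] == neg[0, j]
        ):
            pvals[j] = 1.0
            continue
        pvals[j] = mannwhitneyu(pos[:, j], neg[:, j], alternative="two-sided").pvalue
    return pvals


def _equal_frequency_bins(col: np.ndarray, n_bins: int = 10) -> np.ndarray:
    qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), col, side="right")


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _information_gain(binned: np.ndarray, y: np.ndarray) -> float:
    """Mutual information (bits) between a discretized feature and the class."""
    hy = _entropy(np.bincount(y))
    h_cond = 0.0
    n = len(y)
    for b in np.unique(binned):
        mask = binned == b
        h_cond += mask.sum() / n * _entropy(np.bincount(y[mask]))
    return hy - h_cond


def _ig_gr_scores(X: np.ndarray, y: np.ndarray, ratio: bool, n_bins: int):
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        binned = _equal_frequency_bins(X[:, j], n_bins)
        ig = _information_gain(binned, y)
        if ratio:
            hx = _entropy(np.bincount(binned))
            out[j] = ig / hx if hx > 0 else 0.0
        else:
            out[j] = ig
    return out


def _relieff_scores(
    X: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """ReliefF weights: near-miss separation minus near-hit separation.

    Neighbors by Manhattan distance on standardized features, all instances
    used; per-feature differences normalized by the feature's range.
    """
    Z = _zscore(X)
    n, p = Z.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xn = (X - X.min(axis=0)) / span
    weights = np.zeros(p)
    for i in range(n):
        dists = np.abs(Z - Z[i]).sum(axis=1)
        dists[i] = np.inf
        for cls, sign in ((y[i], -1.0), (1 - y[i], +1.0)):
            members = np.flatnonzero(y == cls)
            members = members[members != i]
            kk = min(k, len(members))
            nearest = members[np.argsort(dists[members], kind="stable")[:kk]]
            weights += sign * np.abs(Xn[nearest] - Xn[i]).mean(axis=0) / n
    return weights


def _rfe_order(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """Reverse elimination order of a one-at-a-time linear-SVM RFE (1 = kept last)."""
    rfe = _SklearnRFE(SVC(kernel="linear", C=C), n_features_to_select=1, step=1)
    rfe.fit(_zscore(X), y)
    return rfe.ranking_.astype(float)


def _gfs_order(X: np.ndarray, y: np.ndarray) -> list[int]:
    """Greedy forward least-squares on the 0/1 label: addition order of features."""
    n, p = X.shape
    yv = y.astype(float)
    selected: list[int] = []
    remaining = list(range(p))
    while remaining:
        best_j, best_rss = None, np.inf
        for j in remaining:
            cols = selected + [j]
            A = np.column_stack([np.ones(n), X[:, cols]])
            _coef, res, rank, _sv = np.linalg.lstsq(A, yv, rcond=None)
            rss = float(res[0]) if res.size else float(
                np.sum((yv - A @ _coef) ** 2)
            )
            if rss < best_rss - 1e-12 or best_j is None:
                best_rss, best_j = rss, j
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def _path_entry_order(X: np.ndarray, y: np.ndarray, l1_ratio: float) -> np.ndarray:
    """Support-entry position of each feature along a descending lambda path.

    100 geometrically spaced lambdas from lambda_max (the smallest value
    zeroing every coefficient) down by three decades. Returns, per feature,
    the index of the first lambda at which it enters the support (large for
    features that never enter).
    """
    Z = _zscore(X)
    yc = y.astype(float) - y.mean()
    n = len(y)
    lam_max = np.max(np.abs(Z.T @ yc)) / (n * l1_ratio)
    alphas = np.geomspace(lam_max, lam_max * 1e-3, 100)
    if l1_ratio == 1.0:
        _, coefs, _ = lasso_path(Z, yc, alphas=alphas)
    else:
        _, coefs, _ = enet_path(Z, yc, alphas=alphas, l1_ratio=l1_ratio)
    p = Z.shape[1]
    entry = np.full(p, coefs.shape[1] + 1, dtype=float)
    nonzero = np.abs(coefs) > 1e-12
    for j in range(p):
        hits = np.flatnonzero(nonzero[j])
        if hits.size:
            entry[j] = hits[0]
    # never-entered features fall back to marginal correlation strength
    never = entry > coefs.shape[1]
    if never.any():
        corr = np.abs(Z.T @ yc) / n
        entry[never] = coefs.shape[1] + 1 + (1.0 - corr[never])
    return entry


def _rf_margin_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> np.ndarray:
    """Permutation importance: drop in average margin after shuffling a feature.

    The margin of an instance is the predicted probability of its true class
    minus that of the other class.
    """
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    pos_col = int(np.flatnonzero(rf.classes_ == 1)[0])

    def mean_margin(M: np.ndarray) -> float:
        proba = rf.predict_proba(M)[:, pos_col]
        margin = np.where(y == 1, proba - (1 - proba), (1 - proba) - proba)
        return float(margin.mean())

    base = mean_margin(X)
    rng = np.random.default_rng(seed)
    imp = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        imp[j] = base - mean_margin(Xp)
    return imp


def rank_features(
    table: FeatureTable,
    method: str,
    params: dict | None = None,
    seed: int = 0,
) -> RankedFeatureList:
    """Rank all features of a labeled table with one base algorithm.

    Every method returns a full permutation of the feature set, rank 1
    being the most relevant feature; tie-breaks are deterministic
    (lexicographic on the feature name). Missing values are imputed with
    the per-feature median before ranking.
    """
    if method not in BASE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {BASE_METHODS}")
    y = _check_labeled(table)
    X = _clean_values(table)
    names = table.feature_names
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    if method == "WT":
        score = _wilcoxon_scores(X, y)
        ordered = _order_by_score(names, score, descending=False)
    elif method in ("IG", "GR"):
        n_bins = params.setdefault("n_bins", 10)
        score = _ig_gr_scores(X, y, ratio=(method == "GR"), n_bins=n_bins)
        ordered = _order_by_score(names, score, descending=True)
    elif method == "RFS":
        k = params.setdefault("k_neighbors", 10)
        score = _relieff_scores(X, y, k, rng)
        ordered = _order_by_score(names, score, descending=True)
    elif method == "RFE":
        C = params.setdefault("C", 1.0)
        score = _rfe_order(X, y, C)
        ordered = _order_by_score(names, score, descending=False)
    elif method == "GFS":
        addition = _gfs_order(X, y)
        score = np.empty(len(names))
        for pos, j in enumerate(addition):
            score[j] = pos + 1
        ordered = _order_by_score(names, score, descending=False)
    elif method in ("LR", "EN"):
        l1_ratio = 1.0 if method == "LR" else params.setdefault("l1_ratio", 0.5)
        params.setdefault("n_lambdas", 100)
        score = _path_entry_order(X, y, l1_ratio)
        ordered = _order_by_score(names, score, descending=False)
    else:  # RF
        n_trees = params.setdefault("n_trees", 500)
        score = _rf_margin_importance(X, y, n_trees, seed)
        ordered = _order_by_score(names, score, descending=True)

    return RankedFeatureList(
        method=method,
        features=ordered,
        scores={names[j]: float(score[j]) for j in range(len(names))},
        params=params,
        seed=seed,
    )


def _check_same_features(lists: list[RankedFeatureList]) -> list[str]:
    if not lists:
        raise ValueError("no rankings to aggregate")
    base = set(lists[0].features)
    for rl in lists[1:]:
        if set(rl.features) != base:
            raise ValueError("rankings cover different feature sets")
    return sorted(base)


def aggregate_mean(lists: list[RankedFeatureList]) -> EnsembleScore:
    """Ens-mean (EFmn): S_f is the average of a feature's ranks over all lists.

    The final ordering is ascending in S_f with lexicographic tie-breaks;
    it coincides with the Borda-count ranking of the same lists.
    """
    features = _check_same_features(lists)
    scores = {
        f: float(np.mean([rl.ranks[f] for rl in lists])) for f in features
    }
    ordering = sorted(features, key=lambda f: (scores[f], f))
    return EnsembleScore("EFmn", scores, B=len(lists), ordering=ordering)


def aggregate_mode(lists: list[RankedFeatureList]) -> EnsembleScore:
    """Ens-voting (EFmd): S_f is the most frequent rank of a feature.

    A multimodal rank distribution resolves to the smallest modal rank; the
    final ordering is ascending in S_f with ties broken by mean rank, then
    lexicographically.
    """
    features = _check_same_features(lists)
    scores: dict[str, float] = {}
    mean_rank: dict[str, float] = {}
    for f in features:
        ranks = [rl.ranks[f] for rl in lists]
        values, counts = np.unique(ranks, return_counts=True)
        scores[f] = float(values[counts == counts.max()].min())
        mean_rank[f] = float(np.mean(ranks))
    ordering = sorted(features, key=lambda f: (scores[f], mean_rank[f], f))
    return EnsembleScore("EFmd", scores, B=len(lists), ordering=ordering)


def top_k(ranking: "RankedFeatureList | EnsembleScore", k: int):
    """The signature of size k: the first k features of a ranking."""
    from lncsig.signatures import Signature

    if k <= 0:
        raise ValueError("k must be positive")
    if isinstance(ranking, EnsembleScore):
        ranking = ranking.to_ranked_list()
    if k > len(ranking.features):
        raise ValueError(f"k={k} exceeds the number of features {len(ranking.features)}")
    return Signature(
        name=f"{ranking.method}_top{k}",
        features=ranking.features[:k],
        source=ranking.method,
    )


def univariate_aupr_table(table: FeatureTable) -> pd.DataFrame:
    """Score each feature alone as a ranking of samples: AUPR (normalized) and AUC.

    The orientation (feature or its negation) maximizing AUPR is chosen per
    feature, since a feature anticorrelated with the class is just as
    useful. Rows come back sorted by AUPR descending.
    """
    y = _check_labeled(table)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = _clean_values(table)
    rows = []
    for j, name in enumerate(table.feature_names):
        fwd = score_metrics(X[:, j], y)
        rev = score_metrics(-X[:, j], y)
        best, orient = (fwd, +1) if fwd.aupr_norm >= rev.aupr_norm else (rev, -1)
        rows.append(
            {
                "feature": name,
                "AUPR": best.aupr_norm,
                "AUC": best.auc,
                "aupr_raw": best.aupr_raw,
                "orientation": orient,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["AUPR", "feature"], ascending=[False, True]
    )
    return df.reset_index(drop=True)
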