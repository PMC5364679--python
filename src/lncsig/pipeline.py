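"""End-to-end signature discovery on a simulated transcriptome.

Chains the full workflow — featurize, collapse collinear features, rank
with several algorithms, aggregate ranks, take the top-k signature, and
cross-validate a classifier on it — the way the individual stages are
meant to compose. Primarily a convenience for examples, calibration
experiments, and reproduction runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lncsig.collinearity import collapse_collinear
from lncsig.evaluation import EvalReport, crossvalidate
from lncsig.features import FeatureTable, build_feature_table
from lncsig.selection import aggregate_mean, rank_features, top_k
from lncsig.signatures import Signature
from lncsig.synthetic_data import SimulationConfig, simulate_transcriptome

__all__ = ["WorkflowResult", "run_signature_workflow"]


@dataclass
class WorkflowResult:
    """Everything the workflow produced, from feature table to evaluation."""

    table: FeatureTable
    reduced: FeatureTable
    signature: Signature
    report: EvalReport
    constant_dropped: list[str] = field(default_factory=list)
    n_clusters: int = 0


def run_signature_workflow(
    config: SimulationConfig,
    k: int = 20,
    methods: tuple[str, ...] = ("WT", "IG", "GR"),
    classifier: str = "SVM",
    folds: int = 10,
    n_boot: int = 30,
) -> WorkflowResult:
    """Simulate, featurize, reduce, select (rank-mean ensemble), evaluate.

    The ensemble signature is the top-k of the mean-rank aggregation over
    the given base methods, computed on the collinearity-reduced table;
    evaluation is a stratified k-fold cross-validation with ROSE-style
    rebalancing of training folds. All stages derive their seeds from
    ``config.seed``.
    """
    sim = simulate_transcriptome(config)
    table = build_feature_table(
        sim.models, tracks=sim.tracks, catalog=sim.catalog, labels=sim.labels
    )
    reduced, clustering, constant = collapse_collinear(
        table, n_boot=n_boot, seed=config.seed
    )
    lists = [rank_features(reduced, m, seed=config.seed) for m in methods]
    signature = top_k(aggregate_mean(lists), min(k, reduced.p))
    report = crossvalidate(
        reduced, signature.features, classifier=classifier, folds=folds,
        seed=config.seed,
    )
    return WorkflowResult(
        table=table,
        reduced=reduced,
        signature=signature,
        report=report,
        constant_dropped=constant,
        n_clusters=len(clustering.clusters),
    )
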