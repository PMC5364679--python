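"""Cross-validate a signature with skew-normalized precision-recall metrics.

At positive:negative skew 0.1 a random ranking already reaches AUPR ~0.09,
and no classifier can fall below the minimum PR curve, so the raw area is
rescaled above that floor: normalized AUPR = (raw - min) / (1 - min).
"""

from lncsig.evaluation import crossvalidate, min_aupr
from lncsig.synthetic_data import planted_feature_table

table = planted_feature_table(n=600, p=10, effect=2.0, skew=0.1, seed=6,
                              n_informative=2)
pi = table.y.mean()
print(f"class skew pi = {pi:.3f}; unachievable-region floor min_aupr = "
      f"{min_aupr(pi):.4f}")

for classifier in ("SVM", "RForest", "NBayes"):
    report = crossvalidate(table, ["f01", "f02"], classifier, folds=10, seed=1)
    agg = report.aggregate
    print(f"{classifier:>7}: raw AUPR {agg['aupr_raw']:.3f}  "
          f"normalized AUPR {agg['aupr_norm']:.3f}  AUC {agg['auc']:.3f}")

print()
print("Training folds are rebalanced (majority downsampling + kernel-smoothed")
print("minority synthesis); test folds keep the natural 0.1 skew, which is")
print("exactly what the normalization makes comparable across datasets.")
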