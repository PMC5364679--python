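"""Case-study validation: neighbor co-expression and Ribosome Release Score.

Simulates a transcriptome in which lncRNAs share an expression factor with
a neighboring coding gene (cis-regulation) and in which ribosome footprints
drop after the stop codon of coding transcripts, then runs both validation
statistics.
"""

from lncsig.synthetic_data import (
    SimulationConfig,
    simulate_coverage,
    simulate_expression,
    simulate_transcriptome,
)
from lncsig.validation import (
    coexpression_contrast,
    neighbor_pairs,
    rrs,
    rrs_contrast,
)

config = SimulationConfig(n_coding=120, n_noncoding=40, co_expr_rho=0.8,
                          ribo_drop=0.1, seed=8)
sim = simulate_transcriptome(config)
lnc = [m for m in sim.models if sim.labels[m.id] == "lncRNA"]
pct = [m for m in sim.models if sim.labels[m.id] == "Other"]

expr = simulate_expression(sim.models, sim.labels, config)
for window in (20, 30, 40):
    lnc_pairs = neighbor_pairs(lnc, pct, window)
    pct_pairs = neighbor_pairs(pct, pct, window)[: len(lnc_pairs) * 4]
    res = coexpression_contrast(expr, lnc_pairs, pct_pairs, low_var_frac=0.5)
    print(f"{window} kb window: {len(res.lnc_pct)} lnc-PCT pairs, "
          f"median |rho| {float(sorted(res.lnc_pct)[len(res.lnc_pct)//2]):.2f} "
          f"vs PCT-PCT {float(sorted(res.pct_pct)[len(res.pct_pct)//2]):.2f}, "
          f"one-tailed p = {res.p_value:.2e}")

profile = simulate_coverage(sim.models, sim.labels, config)
scores = rrs(profile)
coding_rrs = [scores[t] for t in scores.index if sim.labels[t] == "Other"]
lnc_rrs = [scores[t] for t in scores.index if sim.labels[t] == "lncRNA"]
p = rrs_contrast(coding_rrs, lnc_rrs)
print(f"\nRRS: coding median {sorted(coding_rrs)[len(coding_rrs)//2]:.1f} vs "
      f"lncRNA median {sorted(lnc_rrs)[len(lnc_rrs)//2]:.1f}, "
      f"one-tailed p = {p:.2e}")
print()
print("lncRNA-PCT neighbors co-express above the PCT-PCT baseline, and the")
print("post-stop footprint drop gives coding transcripts a much higher RRS.")
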