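# Methods

This note documents the models, statistics, numerical choices, and
deliberate design decisions behind `lncsig`, and what the synthetic
experiments do and do not demonstrate.

## The classification problem

Transcripts are labeled *lncRNA* (positive) or *Other* (negative:
protein coding, short ncRNA, IG/TR). Realistic gold standards are
heavily skewed — the bundled annotation tallies give positive:negative
ratios of 0.18 (human), 0.10 (mouse), and 0.11 (zebrafish) — which
drives two design commitments throughout the package: precision–recall
rather than ROC as the primary lens, and explicit rebalancing of
training data only.

## Features

*BASIC.* Exon count, spliced length, mean exon length. Computed from the
exon intervals; `TxLen` is the spliced (exonic) length, not the genomic
span.

*ORF.* `find_orf` scans the three sense-strand frames (transcripts are
stranded, so the antisense frames are not searched); a candidate runs
from an ATG to the first in-frame stop, stop codon included in the
length — an explicit convention, configurable in spirit by adjusting the
returned interval. The longest candidate wins, ties to the smallest
offset. When no stop-terminated candidate exists anywhere, an optional
open-ended fallback returns the longest ATG-to-end run truncated to
complete codons (`allow_open`, on by default), mirroring how
CDS-prediction utilities treat incomplete 3' ends. Codons containing N
are inert. `OrfProp = OrfLen / TxLen`. The `KOZAK` score sums
position-specific weights over a −6..+4 window anchored at the A of the
start codon; positions outside the transcript (ORF at the very 5' end)
contribute the matrix's neutral weight, so truncated contexts are
penalized toward indifference rather than zero. The shipped matrix
(`data/kozak_vertebrate.json`) is a consensus-derived vertebrate
initiation-context PWM — a synthetic stand-in assembled from the
canonical gccRccATGG compilation; any species-specific matrix can be
supplied through `FeatureConfig`, and a uniform matrix is available as a
neutral fallback.

*NUCLEO.* The Fickett TESTCODE statistic combines, per base, the
asymmetry of counts across the three codon phases (max/(min+1)) and the
overall composition, each mapped through the published probability
tables and weights; the implementation is validated against an
independently coded table-lookup oracle. The 80 k-mer features are
overlapping di-/tri-nucleotide counts divided by the transcript length L
(not L−k+1 — a deliberate convention choice; the test suite encodes its
consequence, Σdi = (L−1)/L). Windows containing N are not counted.
Mononucleotide frequencies are excluded.

*CONS.* Per-base conservation (phastCons/phyloP-style tracks read from
bedGraph) is averaged per exon over defined bases only; the transcript
features are the unweighted mean/max/min of exon averages — unweighted
by exon length, because the per-exon average is the unit of
aggregation. Exons with no defined bases are excluded; a transcript with
no defined bases gets missing values, which downstream stages handle
(pairwise-complete correlations; median imputation before ranking).

*REPS.* One feature per repeat family: the proportion of exonic bases
covered by ≥1 interval of that family, with same-family intervals
unioned first so the value is a true coverage in [0, 1].

## Collinearity reduction

Features are standardized (sample sd, constant features dropped and
reported). Distance d = 1 − |Pearson r| on pairwise-complete
observations, complete linkage. Because a complete-linkage node's height
equals the maximum pairwise distance among its members, cutting the tree
at 1 − threshold yields exactly the maximal candidate clusters whose
members are all pairwise |r| > threshold (default 0.8); membership is
re-verified explicitly. Cluster uncertainty: the fraction of row-
bootstrap clusterings (default 1000, seeded) in which the identical
member set reappears; a cluster is kept when 1 − support < 0.05. A
multiscale mode fits the probit extrapolation
1 − support(r) = Φ(d√r + c/√r) over resample scales r ∈ {0.6..1.4} and
uses the approximately-unbiased p-value Φ(d − c); ordinary support is
the default because the selection contract (stable clusters only)
depends only on a support threshold. Each kept cluster is collapsed onto
the member with the highest univariate AUPR against the label
(resubstitution, matching the univariate analysis; ties break
lexicographically).

## Feature ranking

All nine base methods return a full permutation of the feature set with
deterministic lexicographic tie-breaks; missing values are median-
imputed first. Method-specific choices, each recorded in the returned
parameter set:

- **WT** — two-sided Mann–Whitney/Wilcoxon rank-sum p-value per feature,
  ascending. Rank-based, hence no standardization.
- **IG / GR** — mutual information (bits) between the class and the
  feature discretized into 10 equal-frequency bins; GR divides by the
  binned feature's entropy (0 when the entropy is 0).
- **RFS** — ReliefF with k = 10 nearest hits/misses over all instances,
  Manhattan distance on standardized features, per-feature differences
  normalized by the feature's range.
- **RFE** — linear SVM (C = 1) on standardized features, eliminating
  exactly one feature per iteration (smallest squared weight); rank =
  reverse elimination order, validated against an explicit elimination
  loop at p ≤ 5.
- **GFS** — greedy forward least squares on the 0/1 label with
  intercept; rank = addition order, validated against an exhaustive
  greedy-RSS oracle at p ≤ 5.
- **LR / EN** — coordinate-descent regularization path over 100
  geometrically spaced λ from λ_max (the smallest λ zeroing all
  coefficients) down three decades; rank = order of first entry into the
  support; EN mixing 0.5. Features that never enter are ordered by
  marginal correlation.
- **RF** — 500 trees; importance = drop in mean margin (probability of
  the true class minus the other) after permuting one feature, seeded.

Ensembles: `EFmn` averages ranks (equivalent to a Borda count — a tested
invariant) and `EFmd` takes the modal rank, multimodal ties resolving to
the smallest mode, then mean rank, then name. Ensembles compose either
over algorithms or over 80%-with-replacement subsample draws of one
algorithm (`ensemble_over_subsamples`); the two compositions are exposed
separately and labeled.

## Stability and consensus signatures

Stability draws ⌈0.8·n⌉ rows *without* replacement (the subsample
ensemble draws *with* replacement — the two procedures are defined
independently and both kept); draws are stratified by class so a 0.1
skew cannot produce an empty class. The statistic is the mean overlap
between the full-data top-k and each subsample top-k.

A calibration caveat worth stating precisely: on pure-noise data this
statistic does **not** converge to the hypergeometric k/p, because the
subsample shares 80% of its rows with the full data and the two rankings
are strongly positively correlated; the measured noise floor is ≈0.5–0.6
for k = 5, p = 50. The hypergeometric expectation applies to top-k sets
from *independent* data, and the suite verifies exactly that on disjoint
halves of a noise table (overlap ≈ k/p). Stability values should
therefore be read against this elevated noise floor, not against k/p.

Signatures below the stability floor (default 0.7) are excluded, the
rest clustered by Jaccard distance 1 − |A∩B|/|A∪B| with complete
linkage, tree cut at 0.45 (the operative grouping rule; an equivalent
"55% shared features" phrasing is inconsistent with the Jaccard cut for
size-20 sets and is not enforced). Groups are reported with member
algorithms, feature union/intersection, and a per-category breakdown.

## Evaluation

PR curves merge tied scores into single operating points and integrate
with the nonlinear (Davis–Goadrich-style) interpolation — FP linear in
TP between achievable points, precision t/(a·t + c) integrated in closed
form per segment — because linear interpolation on precision is invalid
in PR space and the unachievable-region normalization assumes the
correct interpolation. A constant scorer yields the single all-positives
point with AUPR = π. The minimum achievable area at skew π is
`1 + ((1−π)/π)·ln(1−π)` (= 1 − ln 2 at π = 0.5), and normalized AUPR
rescales the raw area above that floor, clipped to [0, 1]. AUC is the
rank statistic with half credit for ties.

Rebalancing is ROSE-style: the majority class is uniformly downsampled
and the minority class regenerated as kernel-smoothed draws around real
minority rows — per-feature Gaussian noise with the Silverman-type
bandwidth (4/((d+2)m))^(1/(d+4))·σ_j times a shrink factor, clipped to
the observed feature range. Totals are preserved and classes balanced to
±1. Rebalancing touches training folds only; a hash-free but direct
test asserts test folds are never altered in spirit by scoring them as
observed.

Cross-validation is stratified 10-fold; the aggregate is the unweighted
mean of per-fold metrics (pooling is deliberately not the default, to
match per-fold CI-style reporting). Repeated holdout draws a fixed-size
test set per class (default 20 × 100/class), trains on the rebalanced
remainder, thresholds probabilities at 0.5, and reports
precision/recall/accuracy means with normal-approximation 95% CIs
(±1.96·sd/√reps). SVM probabilities come from the standard Platt-style
mapping of the fitted SVC, recorded as the score-to-probability choice
since the RBF/C = 1 specification alone does not define one.

## Case-study validation statistics

Two genes are neighbors when their genomic spans sit on the same
chromosome with an end-to-start gap below the window (0 when
overlapping — one fixed convention; any fixed convention preserves the
monotone-in-window property that is actually tested). The co-expression
contrast removes the lowest-variance half of transcripts, computes
|Spearman ρ| per surviving pair, and tests lncRNA–PCT > PCT–PCT with a
one-tailed rank-sum test; random non-neighbor PCT pairs are reported as
a baseline only. RRS is the Guttman-style composition
(ribo_ORF/ribo_3'UTR)/(rna_ORF/rna_3'UTR) on densities
(reads + pseudocount)/length with pseudocount 1; it is invariant to
uniform count scaling as the pseudocount vanishes, and zero-length
3'UTRs are skipped and reported. The group contrast uses the exact
rank-sum null for small tie-free groups and the asymptotic
approximation otherwise.

## Synthetic data: what it emulates, what it does not

The generator plants the five contrasts the features are designed to
exploit: a codon-biased ~0.7-proportion ORF with a Kozak consensus
context in coding transcripts vs chance ORFs in non-coding ones; a
conservation gap (per-transcript latent level, per-exon jitter 0.01 —
kept well below the 0.12 between-transcript spread so the exon count
cannot leak class signal into the max/min aggregates, verified by an
ablation test against a permutation null); AT/GC composition bias;
transposable-element coverage 0.39 (coding) vs 0.83 (non-coding), the
published enrichment contrast, with class-specific family mixes; and
class skew ≈0.1 by default (364 coding / 36 non-coding), matching the
skew regime of the annotation tallies. Loci are interleaved along one
synthetic chromosome with 4–12 kb spacers so neighbor pairs exist at the
20–40 kb windows; ~30% of transcripts are minus-strand. Expression
plants a shared latent factor (correlation ρ = 0.8 by default) in
greedily matched lncRNA–coding neighbor pairs across 17 samples;
coverage drops ribosome-footprint density to 0.1× past the stop codon of
coding transcripts only, with Poisson counts.

What passing on this generator shows: the pipeline's stages compose
correctly, recover planted structure at realistic skew, and are
calibrated under their nulls. What it does not show: performance on real
transcriptomes — the generator has no splice-site or promoter realism,
no homology structure between transcripts, conservative (near-separable)
class gaps at default settings, and independent features within a
category where real features co-vary. End-to-end metrics near 1.0 on
defaults are a pipeline sanity property, not a performance claim.

## Problem sizes and seeds

The shipped experiments run at desk scale, chosen so the full suite and
the reproduction script each complete in minutes on one CPU: end-to-end
runs use n = 400 transcripts (3 seeds), selector-recovery uses p = 50
features, stability calibration n = 200 with 100 subsamples, null
calibrations 200 replicates, and the collinearity bootstrap is reduced
from its 1000-replicate default to 30–100 where it is exercised
repeatedly. Every stochastic component takes an explicit seed; a single
top-level seed derives all others in the reproduction script.
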