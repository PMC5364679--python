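"""Bundled reference tallies from published annotation and case-study tables.

Two small sets of printed numbers travel with the package so that the
arithmetic they imply (class skews, prediction-overlap fractions) can be
recomputed rather than hard-coded downstream:

* the reliably annotated transcript counts per species (lncRNA positives
  vs all other reliable transcripts) used as gold standards for human
  (hg38), mouse (mm10), and zebrafish (zv9);
* the zebrafish case-study tallies: of 1133 published multi-exonic
  lncRNAs from de novo assembled embryogenesis transcriptomes, how many
  were recovered by classifiers trained on each feature set.

Also here: the feature list of the IseeRNA tool, supported as a named
signature configuration for comparison runs.
"""

from __future__ import annotations

__all__ = [
    "GOLD_STANDARD_COUNTS",
    "CASE_STUDY_TALLIES",
    "class_skew",
    "case_study_fraction",
    "iseerna_signature",
]

# (lncRNA positives, all other reliable transcripts) per species
GOLD_STANDARD_COUNTS: dict[str, tuple[int, int]] = {
    "human": (25821, 139708),
    "mouse": (8155, 79486),
    "zebrafish": (1769, 16754),
}

# zebrafish de novo case study: classifier predictions vs the published
# 1133-lncRNA reference set, per training feature set
CASE_STUDY_TALLIES: dict[str, dict[str, int]] = {
    "signature_1": {"predicted": 17154, "reference": 1133, "intersection": 1035},
    "signature_2": {"predicted": 17305, "reference": 1133, "intersection": 995},
    "signature_3": {"predicted": 17198, "reference": 1133, "intersection": 1039},
    "signature_4": {"predicted": 18615, "reference": 1133, "intersection": 962},
    "iseerna": {"predicted": 17077, "reference": 1133, "intersection": 951},
    "all_features": {"predicted": 9366, "reference": 1133, "intersection": 738},
}


def class_skew(species: str) -> float:
    """Positives / negatives ratio of the species' gold-standard annotation."""
    try:
        pos, neg = GOLD_STANDARD_COUNTS[species]
    except KeyError:
        raise KeyError(
            f"unknown species {species!r}; choose from {sorted(GOLD_STANDARD_COUNTS)}"
        ) from None
    return pos / neg


def case_study_fraction(feature_set: str) -> float:
    """Fraction of the published lncRNA reference recovered by one feature set."""
    try:
        row = CASE_STUDY_TALLIES[feature_set]
    except KeyError:
        raise KeyError(
            f"unknown feature set {feature_set!r}; choose from {sorted(CASE_STUDY_TALLIES)}"
        ) from None
    return row["intersection"] / row["reference"]


def iseerna_signature(phastcons_track: str = "ph8") -> list[str]:
    """The IseeRNA feature list as a named signature over this package's names.

    Conservation score (phastCons exon-mean for the given track), ORF
    length and proportion, and the GC, CT, TAG, TGT, ACG, TCG k-mer
    frequencies.
    """
    return [
        f"{phastcons_track}m",
        "OrfLen",
        "OrfProp",
        "GC",
        "CT",
        "TAG",
        "TGT",
        "ACG",
        "TCG",
    ]
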