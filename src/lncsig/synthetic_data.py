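"""Synthetic two-class transcriptomes with planted coding/non-coding structure.

The generator emulates the statistical contrasts that separate lncRNAs
from coding transcripts, so every pipeline stage can be exercised and
calibrated without any genome download:

* coding transcripts carry a long codon-biased ORF (target proportion
  ~0.7 of the transcript) with a Kozak consensus context, elevated
  exonic conservation, and moderate transposable-element coverage;
* non-coding transcripts have only chance ORFs, lower conservation,
  and higher TE coverage (defaults 0.39 vs 0.83 of the sequence,
  the enrichment contrast reported for protein-coding vs lncRNA
  sequences), with a different repeat-family mix;
* neighbor lncRNA-PCT gene pairs share a latent expression factor
  (planted Spearman correlation), and ribosome-footprint coverage drops
  past the stop codon for coding transcripts only.

Everything is driven by a single seeded generator, so outputs are
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from lncsig.features import POSITIVE_LABEL, NEGATIVE_LABEL, FeatureTable, find_orf
from lncsig.transcript_io import (
    GenomicInterval,
    RepeatCatalog,
    ScoreTrack,
    TranscriptModel,
)
from lncsig.validation import CoverageProfile, ExpressionMatrix, neighbor_pairs

__all__ = [
    "SimulationConfig",
    "SimulatedTranscriptome",
    "simulate_transcriptome",
    "simulate_expression",
    "simulate_coverage",
    "planted_feature_table",
    "PLANTED_FEATURE",
    "REPEAT_FAMILIES",
]

REPEAT_FAMILIES = [
    "DNA.TcMar",
    "DNA.hAT",
    "LINE.L1",
    "LTR.ERV1",
    "RC.Helitron",
    "SINE.Alu",
]
# family sampling weights per class; non-coding leans on SINE/LINE, coding on DNA/LTR
_FAMILY_W_CODING = np.array([0.25, 0.20, 0.10, 0.25, 0.10, 0.10])
_FAMILY_W_NONCODING = np.array([0.05, 0.10, 0.30, 0.10, 0.10, 0.35])

_STOPS = ("TAA", "TAG", "TGA")
PLANTED_FEATURE = "f01"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic transcriptome.

    Defaults mirror a skewed vertebrate annotation: positive:negative
    ratio ~0.1, a ~0.7 ORF proportion for coding transcripts, a
    conservation gap between classes, and the 0.39 vs 0.83 TE-coverage
    contrast between coding and lncRNA sequence.
    """

    n_coding: int = 364
    n_noncoding: int = 36
    orf_frac_coding: float = 0.7
    kozak_strength: float = 0.9
    cons_mean_coding: float = 0.65
    cons_mean_noncoding: float = 0.30
    repeat_rate_coding: float = 0.39
    repeat_rate_noncoding: float = 0.83
    kmer_bias: float = 0.5
    co_expr_rho: float = 0.8
    ribo_drop: float = 0.1
    n_samples: int = 17
    track_name: str = "ph8"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coding <= 0 or self.n_noncoding <= 0:
            raise ValueError("both class counts must be positive")
        for name in (
            "orf_frac_coding", "kozak_strength", "cons_mean_coding",
            "cons_mean_noncoding", "repeat_rate_coding", "repeat_rate_noncoding",
            "kmer_bias", "co_expr_rho", "ribo_drop",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimulatedTranscriptome:
    """Transcript models with sequences plus the track/catalog/label context."""

    models: list[TranscriptModel]
    genome: dict[str, str]
    tracks: dict[str, ScoreTrack]
    catalog: RepeatCatalog
    labels: dict[str, str] = field(default_factory=dict)

    def label_series(self) -> pd.Series:
        return pd.Series(self.labels)


def _random_seq(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _coding_orf(rng: np.random.Generator, n_codons: int, bias: float) -> str:
    """ATG + biased sense codons + stop; in-frame stops excluded by construction."""
    codons = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in _STOPS and a + b + c != "ATG"
    ]
    gc_content = np.array([sum(ch in "GC" for ch in cod) / 3 for cod in codons])
    weights = (1.0 - bias) + bias * (0.5 + gc_content)
    weights = weights / weights.sum()
    body = rng.choice(len(codons), size=max(n_codons - 2, 1), p=weights)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(codons[i] for i in body) + stop


def _split_lengths(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    if parts * minimum >= total:
        parts = max(1, total // (2 * minimum))
    if parts == 1:
        return [total]
    free = total - parts * minimum
    cuts = np.sort(rng.integers(0, free + 1, size=parts - 1))
    chunks = np.diff(np.r_[0, cuts, free])
    return [minimum + int(c) for c in chunks]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_transcriptome(config: SimulationConfig) -> SimulatedTranscriptome:
    """Generate a labeled transcriptome, toy genome, conservation track, and repeats.

    Loci are laid out sequentially on one synthetic chromosome with
    4-12 kb intergenic spacers (so neighbor pairs exist at the 20-40 kb
    windows used downstream). Roughly 30% of transcripts land on the minus
    strand, exercising the strand logic of sequence extraction.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chrS"
    genome_parts: list[str] = []
    cursor = 0
    models: list[TranscriptModel] = []
    labels: dict[str, str] = {}
    track = ScoreTrack()
    catalog = RepeatCatalog()
    base_probs = {
        True: np.array([0.22, 0.28, 0.28, 0.22]),   # coding background, GC-leaning
        False: np.array([0.30, 0.20, 0.20, 0.30]),  # non-coding, AT-leaning
    }

    # interleave the classes along the chromosome so lncRNA loci have
    # coding neighbors within the co-expression windows
    order = [True] * config.n_coding + [False] * config.n_noncoding
    order = [order[j] for j in rng.permutation(len(order))]
    for i, is_coding in enumerate(order):
        tid = f"tx{i:05d}"
        label = NEGATIVE_LABEL if is_coding else POSITIVE_LABEL
        if is_coding:
            tx_len = int(np.clip(rng.lognormal(7.3, 0.30), 400, 4000))
            n_exons = 1 + rng.poisson(4)
        else:
            tx_len = int(np.clip(rng.lognormal(6.7, 0.45), 300, 3000))
            n_exons = 1 + rng.poisson(1.2)

        if is_coding:
            n_codons = max(10, int(round(config.orf_frac_coding * tx_len / 3.0)))
            orf_seq = _coding_orf(rng, n_codons, config.kmer_bias)
            utr3_len = max(30, int(0.6 * (tx_len - len(orf_seq))))
            utr5_len = max(10, tx_len - len(orf_seq) - utr3_len)
            utr5 = _random_seq(rng, utr5_len, base_probs[True])
            if rng.random() < config.kozak_strength and utr5_len >= 6:
                utr5 = utr5[:-6] + "GCCACC"
            utr3 = _random_seq(rng, utr3_len, base_probs[True])
            seq = utr5 + orf_seq + utr3
            tx_len = len(seq)
        else:
            seq = _random_seq(rng, tx_len, base_probs[False])

        exon_lens = _split_lengths(rng, tx_len, n_exons, minimum=40)
        strand = "+" if rng.random() < 0.7 else "-"
        genomic_seq = seq if strand == "+" else _revcomp(seq)

        intervals = []
        offset = 0
        # genomic-order exon lengths; content comes from the genomic-strand sequence
        glens = exon_lens if strand == "+" else exon_lens[::-1]
        for li, elen in enumerate(glens):
            if li > 0:
                intron = int(rng.integers(60, 220))
                genome_parts.append(_random_seq(rng, intron, base_probs[is_coding]))
                cursor += intron
            start = cursor
            genome_parts.append(genomic_seq[offset : offset + elen])
            offset += elen
            cursor += elen
            intervals.append(GenomicInterval(chrom, start, cursor, strand))

        model = TranscriptModel(tid, f"gene{i:05d}", intervals, sequence=seq)
        models.append(model)
        labels[tid] = label

        cons_mean = config.cons_mean_coding if is_coding else config.cons_mean_noncoding
        # per-transcript latent level with small per-exon jitter; the jitter
        # must stay well below the between-transcript spread or the exon
        # count leaks class signal into the max/min-of-exon-means features
        tx_cons = rng.normal(cons_mean, 0.12)
        for iv in intervals:
            val = float(np.clip(rng.normal(tx_cons, 0.01), 0.0, 1.0))
            track.add(chrom, iv.start, iv.end, round(val, 4))

        rate = config.repeat_rate_coding if is_coding else config.repeat_rate_noncoding
        fam_w = _FAMILY_W_CODING if is_coding else _FAMILY_W_NONCODING
        target = rate * tx_len
        covered = 0.0
        guard = 0
        while covered < target and guard < 200:
            guard += 1
            iv = intervals[rng.integers(0, len(intervals))]
            rep_len = int(min(len(iv), rng.integers(80, 320)))
            rep_start = int(iv.start + rng.integers(0, len(iv) - rep_len + 1))
            fam = REPEAT_FAMILIES[rng.choice(len(REPEAT_FAMILIES), p=fam_w)]
            catalog.entries.append(
                (GenomicInterval(chrom, rep_start, rep_start + rep_len), fam)
            )
            covered += rep_len

        spacer = int(rng.integers(4000, 12000))
        genome_parts.append(_random_seq(rng, spacer, np.full(4, 0.25)))
        cursor += spacer

    catalog.entries.sort(key=lambda e: (e[0].chrom, e[0].start, e[0].end, e[1]))
    genome = {chrom: "".join(genome_parts)}
    return SimulatedTranscriptome(
        models=models,
        genome=genome,
        tracks={config.track_name: track},
        catalog=catalog,
        labels=labels,
    )


def simulate_expression(
    models: list[TranscriptModel],
    labels: dict[str, str],
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Expression matrix with planted correlation on neighbor lncRNA-PCT pairs.

    Each lncRNA is paired (greedily, at most once) with a neighboring
    coding gene within 20 kb; the pair shares a latent profile so that
    their correlation equals ``co_expr_rho``. All other transcripts are
    independent. Values are exponentiated normals, keeping them positive
    without changing rank correlations.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_s = config.n_samples
    lnc = [m for m in models if labels[m.id] == POSITIVE_LABEL]
    pct = [m for m in models if labels[m.id] == NEGATIVE_LABEL]
    profiles = {m.id: rng.standard_normal(n_s) for m in models}

    used_pct: set[str] = set()
    rho = config.co_expr_rho
    for a, b in neighbor_pairs(lnc, pct, window_kb=20):
        if b in used_pct:
            continue
        used_pct.add(b)
        latent = profiles[b]
        noise = rng.standard_normal(n_s)
        profiles[a] = rho * latent + math.sqrt(1 - rho**2) * noise

    df = pd.DataFrame(
        {f"s{j:02d}": [math.exp(profiles[m.id][j]) for m in models] for j in range(n_s)},
        index=[m.id for m in models],
    )
    return ExpressionMatrix(df)


def simulate_coverage(
    models: list[TranscriptModel],
    labels: dict[str, str],
    config: SimulationConfig,
    base_rate: float = 0.5,
    rna_rate: float = 0.3,
) -> CoverageProfile:
    """Ribo-seq and mRNA-seq per-base Poisson counts over each transcript.

    Coding transcripts drop to ``ribo_drop`` of their ORF footprint density
    past the stop codon; non-coding transcripts keep a uniform footprint
    rate. mRNA coverage is uniform for both. Transcripts without an ORF or
    without 3'UTR room are omitted.
    """
    rng = np.random.default_rng(config.seed + 2)
    profile = CoverageProfile()
    for m in models:
        orf = find_orf(m.sequence, allow_open=False)
        if orf is None:
            continue
        L = m.length
        if L - orf.end < 10:
            continue
        ribo_rate = np.full(L, base_rate)
        if labels[m.id] == NEGATIVE_LABEL:  # coding: post-stop footprint drop
            ribo_rate[orf.end :] = base_rate * config.ribo_drop
        ribo = rng.poisson(ribo_rate).astype(float)
        rna = rng.poisson(np.full(L, rna_rate)).astype(float)
        profile.add(m.id, ribo, rna, (orf.start, orf.end), (orf.end, L))
    return profile


def planted_feature_table(
    n: int = 500,
    p: int = 50,
    effect: float = 2.0,
    skew: float = 0.1,
    seed: int = 0,
    nan_frac: float = 0.0,
    n_informative: int = 1,
) -> FeatureTable:
    """Gaussian-noise feature table with planted discriminative features.

    The first ``n_informative`` features (``f01``, ``f02``, ...) are shifted
    by ``effect`` standard deviations in the positive (lncRNA) class; all
    other features are pure noise. ``skew`` is the positive:negative ratio.
    Used for selector-recovery and null calibration experiments.
    """
    rng = np.random.default_rng(seed)
    n_pos = max(2, int(round(n * skew / (1.0 + skew))))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    X = rng.standard_normal((n, p))
    X[:, :n_informative] += effect * y[:, None]
    if nan_frac > 0:
        mask = rng.random((n, p)) < nan_frac
        X[mask] = np.nan
    names = [f"f{j + 1:02d}" for j in range(p)]
    df = pd.DataFrame(X, index=[f"t{i:04d}" for i in range(n)], columns=names)
    lab = pd.Series(
        np.where(y == 1, POSITIVE_LABEL, NEGATIVE_LABEL), index=df.index
    )
    perm = rng.permutation(n)
    return FeatureTable(df.iloc[perm], lab.iloc[perm])
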