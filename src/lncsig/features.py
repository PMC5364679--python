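"""Sequence- and annotation-derived transcript features.

Five feature categories are computed per transcript:

* BASIC — exon count (``TxNex``), spliced length (``TxLen``), mean exon
  length (``TxExLenAvg``);
* ORF — longest open-reading-frame length (``OrfLen``), its fraction of
  the transcript (``OrfProp``), and a position-weight-matrix score of the
  Kozak initiation context (``KOZAK``);
* CONS — mean/max/min of per-exon averages of a per-base conservation
  track (e.g. ``ph8m``/``ph8mx``/``ph8mn`` for an 8-way phastCons track);
* NUCLEO — the Fickett TESTCODE statistic (``FickScore``) plus the 80
  overlapping di-/tri-nucleotide frequencies, each an occurrence count
  divided by transcript length;
* REPS — for each configured repeat family, the proportion of exonic
  bases covered by repeats of that family (e.g. ``SINE.Alu``).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from lncsig.transcript_io import RepeatCatalog, ScoreTrack, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "KozakMatrix",
    "OrfCall",
    "FeatureConfig",
    "DINUCLEOTIDES",
    "TRINUCLEOTIDES",
    "basic_features",
    "find_orf",
    "orf_features",
    "fickett_score",
    "kmer_frequencies",
    "conservation_features",
    "repeat_features",
    "build_feature_table",
]

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DINUCLEOTIDES = ["".join(p) for p in itertools.product(BASES, repeat=2)]
TRINUCLEOTIDES = ["".join(p) for p in itertools.product(BASES, repeat=3)]

POSITIVE_LABEL = "lncRNA"
NEGATIVE_LABEL = "Other"


@dataclass
class FeatureTable:
    """Transcripts x named features, with optional binary class labels.

    ``labels``, when present, take values ``"lncRNA"`` (positive class)
    and ``"Other"``.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate transcript ids")
        self.values = self.values.astype(float)
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.index)

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Binary label vector: 1 for the lncRNA class, 0 otherwise."""
        if self.labels is None:
            raise ValueError("table has no class labels")
        return (self.labels == POSITIVE_LABEL).to_numpy().astype(int)

    def select(self, features: list[str]) -> "FeatureTable":
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise KeyError(f"features absent from table: {missing}")
        return FeatureTable(self.values[list(features)].copy(), self.labels)

    def subset_rows(self, idx) -> "FeatureTable":
        vals = self.values.iloc[idx]
        labs = self.labels.iloc[idx] if self.labels is not None else None
        return FeatureTable(vals.copy(), labs.copy() if labs is not None else None)

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        if self.labels is not None:
            df["label"] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        labels = None
        if "label" in df.columns:
            labels = df["label"].astype(str)
            df = df.drop(columns=["label"])
        return cls(df, labels)

    def equals(self, other: "FeatureTable", tol: float = 1e-12) -> bool:
        if self.feature_names != other.feature_names or self.ids != other.ids:
            return False
        a, b = self.values.to_numpy(), other.values.to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, atol=tol, equal_nan=False) | both_nan
        if not close.all():
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        return self.labels is None or self.labels.equals(other.labels)


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame located on the transcript's sense strand.

    ``start`` is the 0-based offset of the A of ATG; ``end`` is one past the
    stop codon (or past the last complete codon for an open-ended call).
    """

    start: int
    end: int
    has_stop: bool

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length not a multiple of 3")

    @property
    def frame(self) -> int:
        return self.start % 3

    def __len__(self) -> int:
        return self.end - self.start


class KozakMatrix:
    """Position-specific weight matrix for the translation-initiation context.

    Offsets are relative to the A of the start codon. Bases not in the
    matrix (e.g. N) and window positions outside the transcript contribute
    the ``neutral`` weight.
    """

    def __init__(
        self, weights: dict[int, dict[str, float]], neutral: float = 0.25
    ) -> None:
        for off, row in weights.items():
            for b, w in row.items():
                if not np.isfinite(w):
                    raise ValueError(f"non-finite weight at offset {off}, base {b}")
        offsets = sorted(weights)
        if not (min(offsets) <= 0 and max(offsets) >= 2):
            raise ValueError("window must cover the ATG (offsets 0..2)")
        self.weights = {off: dict(weights[off]) for off in offsets}
        self.neutral = float(neutral)

    @property
    def window(self) -> int:
        return len(self.weights)

    @classmethod
    def uniform(cls, weight: float = 0.25, offsets=range(-6, 4)) -> "KozakMatrix":
        return cls({off: {b: weight for b in BASES} for off in offsets}, neutral=weight)

    @classmethod
    def default(cls) -> "KozakMatrix":
        """Consensus-derived vertebrate initiation-context matrix shipped with the package."""
        raw = json.loads(
            resources.files("lncsig.data").joinpath("kozak_vertebrate.json").read_text()
        )
        weights = {
            int(row["offset"]): {b: float(row[b]) for b in BASES}
            for row in raw["positions"]
        }
        return cls(weights, neutral=float(raw["neutral"]))

    def score(self, sequence: str, orf_start: int) -> float:
        total = 0.0
        for off, row in self.weights.items():
            pos = orf_start + off
            if 0 <= pos < len(sequence):
                total += row.get(sequence[pos], self.neutral)
            else:
                total += self.neutral
        return total


@dataclass
class FeatureConfig:
    """Featurization knobs: Kozak matrix, open-ended ORF fallback, repeat vocabulary."""

    kozak: KozakMatrix = field(default_factory=KozakMatrix.default)
    allow_open_orf: bool = True
    repeat_families: list[str] | None = None  # default: families present in the catalog


def basic_features(model: TranscriptModel) -> dict[str, float]:
    """Exon count, spliced transcript length, and mean exon length."""
    if not model.intervals:
        raise ValueError(f"{model.id}: transcript has no exons")
    n_ex = len(model.intervals)
    tx_len = model.length
    return {"TxNex": float(n_ex), "TxLen": float(tx_len), "TxExLenAvg": tx_len / n_ex}


def find_orf(sequence: str, allow_open: bool = True) -> OrfCall | None:
    """Locate the longest ORF across the three sense-strand reading frames.

    A candidate runs from an ATG to the first in-frame stop codon
    (TAA/TAG/TGA), stop included in its length. The longest candidate wins;
    ties break toward the smallest start offset. With ``allow_open`` and no
    stop-terminated candidate anywhere, the longest ATG-to-end run truncated
    to complete codons is returned with ``has_stop=False``. Codons containing
    N are neither starts nor stops. Returns ``None`` when no ATG exists.
    """
    sequence = sequence.upper()
    L = len(sequence)
    best: OrfCall | None = None
    best_open: OrfCall | None = None

    def better(cand: OrfCall, cur: OrfCall | None) -> bool:
        if cur is None:
            return True
        return (len(cand), -cand.start) > (len(cur), -cur.start)

    for frame in range(3):
        open_start: int | None = None
        pos = frame
        while pos + 3 <= L:
            codon = sequence[pos : pos + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif codon in STOP_CODONS:
                cand = OrfCall(open_start, pos + 3, True)
                if better(cand, best):
                    best = cand
                open_start = None
            pos += 3
        if allow_open and open_start is not None:
            cand = OrfCall(open_start, pos, False)
            if better(cand, best_open):
                best_open = cand
    return best if best is not None else best_open


def orf_features(
    model: TranscriptModel, orf: OrfCall | None, kozak: KozakMatrix
) -> dict[str, float]:
    """ORF length, ORF proportion of the transcript, and Kozak context score."""
    if orf is None:
        return {"OrfLen": 0.0, "OrfProp": 0.0, "KOZAK": 0.0}
    tx_len = model.length
    orf_len = len(orf)
    return {
        "OrfLen": float(orf_len),
        "OrfProp": orf_len / tx_len,
        "KOZAK": kozak.score(model.sequence, orf.start),
    }


# Fickett (1982) TESTCODE lookup tables: probability that a window with the
# given position-asymmetry / composition parameter comes from a coding
# sequence, plus per-base weights. Parameter thresholds are scanned high to
# low; the first threshold <= value selects the bin.
_FICKETT_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_FICKETT_POSITION_PARAM = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_FICKETT_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_FICKETT_CONTENT_PARAM = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _fickett_lookup(value: float, params: list[float], probs: list[float]) -> float:
    for threshold, prob in zip(params, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_position_parameter(sequence: str, base: str) -> float:
    """Codon-phase asymmetry of one base: max phase count / (min phase count + 1)."""
    counts = [sequence[phase::3].count(base) for phase in range(3)]
    return max(counts) / (min(counts) + 1.0)


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE coding-potential statistic of a nucleotide sequence.

    Combines, for each of the four bases, the asymmetry of its counts across
    the three codon phases and its overall composition, each mapped through
    the published probability tables and weighted. Higher values indicate
    coding-like compositional bias. Deterministic; N bases are ignored.
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    score = 0.0
    L = len(sequence)
    for base in BASES:
        pos_param = fickett_position_parameter(sequence, base)
        score += _fickett_lookup(
            pos_param, _FICKETT_POSITION_PARAM, _FICKETT_POSITION_PROB[base]
        ) * _FICKETT_POSITION_WEIGHT[base]
        content = sequence.count(base) / L
        score += _fickett_lookup(
            content, _FICKETT_CONTENT_PARAM, _FICKETT_CONTENT_PROB[base]
        ) * _FICKETT_CONTENT_WEIGHT[base]
    return score


def kmer_frequencies(sequence: str) -> dict[str, float]:
    """Overlapping di-/tri-nucleotide frequencies: count / transcript length.

    Windows containing a base outside {A,C,G,T} are not counted. The
    denominator is the transcript length L (not L-k+1), so frequencies sum
    to (L-1)/L for dinucleotides and (L-2)/L for trinucleotides on clean
    sequences.
    """
    sequence = sequence.upper()
    L = len(sequence)
    out = {kmer: 0.0 for kmer in DINUCLEOTIDES}
    out.update({kmer: 0.0 for kmer in TRINUCLEOTIDES})
    if L == 0:
        return out
    for k in (2, 3):
        for i in range(L - k + 1):
            window = sequence[i : i + k]
            if window in out:
                out[window] += 1.0
    return {kmer: count / L for kmer, count in out.items()}


def conservation_features(
    model: TranscriptModel, track: ScoreTrack, track_name: str
) -> dict[str, float]:
    """Mean, max, and min of per-exon average conservation scores.

    Each exon is averaged over its defined bases; exons with no defined
    bases are excluded; the per-exon averages are combined unweighted. A
    transcript with no defined bases at all yields missing values.
    """
    exon_means = []
    for iv in model.intervals:
        vals = track.values(iv.chrom, iv.start, iv.end)
        if len(vals):
            exon_means.append(float(np.mean(vals)))
    if not exon_means:
        nan = float("nan")
        return {f"{track_name}m": nan, f"{track_name}mx": nan, f"{track_name}mn": nan}
    return {
        f"{track_name}m": float(np.mean(exon_means)),
        f"{track_name}mx": float(np.max(exon_means)),
        f"{track_name}mn": float(np.min(exon_means)),
    }


def repeat_features(
    model: TranscriptModel, catalog: RepeatCatalog, families: list[str]
) -> dict[str, float]:
    """Per-family proportion of exonic bases covered by repeats of that family.

    Overlapping same-family intervals are unioned before counting, so the
    value is a true coverage proportion in [0, 1].
    """
    by_family = catalog.by_family(model.chrom)
    tx_len = model.length
    out = {}
    for fam in families:
        intervals = by_family.get(fam, [])
        covered = 0
        if intervals:
            merged: list[list[int]] = []
            for s, e in sorted(intervals):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for iv in model.intervals:
                for s, e in merged:
                    covered += max(0, min(e, iv.end) - max(s, iv.start))
        out[fam] = covered / tx_len
    return out


def build_feature_table(
    models: list[TranscriptModel],
    tracks: dict[str, ScoreTrack] | None = None,
    catalog: RepeatCatalog | None = None,
    config: FeatureConfig | None = None,
    labels: dict[str, str] | None = None,
) -> FeatureTable:
    """Featurize transcripts into a table with a deterministic column order.

    Columns: BASIC (3), ORF (3), CONS (3 per track, tracks in sorted name
    order), NUCLEO (FickScore + 80 k-mers), REPS (one per family). Tracks
    and catalog are optional; their column blocks are simply absent when
    not supplied. Models must carry spliced sequences.
    """
    config = config or FeatureConfig()
    tracks = tracks or {}
    ids = [m.id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids")
    if catalog is not None:
        families = config.repeat_families or catalog.families
    else:
        families = []
        if config.repeat_families:
            logger.info("repeat families configured but no catalog supplied; REPS skipped")
    if not tracks:
        logger.info("no conservation tracks supplied; CONS features skipped")

    rows = []
    for m in models:
        if m.sequence is None:
            raise ValueError(f"{m.id}: model has no spliced sequence")
        row: dict[str, float] = {}
        row.update(basic_features(m))
        orf = find_orf(m.sequence, allow_open=config.allow_open_orf)
        row.update(orf_features(m, orf, config.kozak))
        for name in sorted(tracks):
            row.update(conservation_features(m, tracks[name], name))
        row["FickScore"] = fickett_score(m.sequence)
        row.update(kmer_frequencies(m.sequence))
        if families:
            row.update(repeat_features(m, catalog, families))
        rows.append(row)

    columns = ["TxNex", "TxLen", "TxExLenAvg", "OrfLen", "OrfProp", "KOZAK"]
    for name in sorted(tracks):
        columns += [f"{name}m", f"{name}mx", f"{name}mn"]
    columns += ["FickScore"] + DINUCLEOTIDES + TRINUCLEOTIDES
    columns += sorted(families)

    df = pd.DataFrame(rows, index=ids)[columns]
    label_series = None
    if labels is not None:
        label_series = pd.Series({i: labels[i] for i in ids}, name="label")
    return FeatureTable(df, label_series)
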