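"""Readers and writers for the external formats the toolkit touches.

All internal coordinates are 0-based half-open. GTF and RepeatMasker
``.out`` use 1-based closed coordinates; the conversion happens here, at
the I/O boundary, and nowhere else. Chromosome names are treated as
opaque strings; a rename map can be applied on read when annotation and
genome use different naming schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "ScoreTrack",
    "RepeatCatalog",
    "read_gtf",
    "read_fasta",
    "read_bedgraph",
    "read_repeatmasker",
    "splice_sequence",
    "write_feature_table",
    "read_feature_table",
    "write_gtf",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A transcript: ordered exons on a genome plus its spliced sense-strand sequence.

    Exons are kept in genomic order regardless of strand; ``sequence``, when
    set, is the spliced transcript read 5'->3' on the sense strand (i.e. the
    concatenated exon sequence, reverse-complemented as a whole for minus-
    strand models).
    """

    id: str
    gene_id: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.intervals:
            chroms = {iv.chrom for iv in self.intervals}
            strands = {iv.strand for iv in self.intervals}
            if len(chroms) > 1:
                raise ValueError(f"{self.id}: exons on multiple chromosomes {chroms}")
            if len(strands) > 1:
                raise ValueError(f"{self.id}: exons on mixed strands")
            ivs = sorted(self.intervals, key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError(f"{self.id}: overlapping exons")
            self.intervals = ivs
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"{self.id}: sequence length {len(self.sequence)} != exon total {self.length}"
                )

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint from first exon start to last exon end."""
        return GenomicInterval(
            self.chrom, self.intervals[0].start, self.intervals[-1].end, self.strand
        )


class ScoreTrack:
    """Sparse per-base float scores, e.g. phastCons/phyloP conservation.

    Bases absent from the track are undefined and excluded from all
    aggregations downstream.
    """

    def __init__(self) -> None:
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._raw: dict[str, list[tuple[int, int, float]]] = {}

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        if not np.isfinite(value):
            raise ValueError(f"non-finite score at {chrom}:{start}-{end}")
        self._raw.setdefault(chrom, []).append((start, end, float(value)))
        self._chroms.pop(chrom, None)

    def _compiled(self, chrom: str):
        if chrom not in self._chroms:
            rows = sorted(self._raw.get(chrom, []))
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=float)
            self._chroms[chrom] = (starts, ends, vals)
        return self._chroms[chrom]

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over ``[start, end)``; defined bases only."""
        starts, ends, vals = self._compiled(chrom)
        if len(starts) == 0:
            return np.empty(0)
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        out: list[np.ndarray] = []
        for i in range(lo, hi):
            a, b = max(starts[i], start), min(ends[i], end)
            if a < b:
                out.append(np.full(b - a, vals[i]))
        return np.concatenate(out) if out else np.empty(0)


@dataclass
class RepeatCatalog:
    """Repeat annotations as (interval, family) pairs.

    ``dropped`` counts input records whose repeat family was not in the
    configured family vocabulary.
    """

    entries: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    dropped: int = 0

    @property
    def families(self) -> list[str]:
        return sorted({fam for _, fam in self.entries})

    def by_family(self, chrom: str) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for iv, fam in self.entries:
            if iv.chrom == chrom:
                out.setdefault(fam, []).append((iv.start, iv.end))
        return out


def read_gtf(path, rename: dict[str, str] | None = None) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models (sequences unset).

    1-based closed GTF coordinates become 0-based half-open. Exon records
    missing ``transcript_id`` are rejected with a logged warning; a transcript
    whose exons sit on mixed strands raises ``ValueError``. Models keep the
    file's transcript order with exons in genomic order.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path), ":memory:",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except EmptyInputError:
        return []
    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []
    for rec in db.features_of_type("exon", order_by=None):
        tids = rec.attributes.get("transcript_id")
        if not tids:
            logger.warning(
                "%s: exon at %s:%d-%d without transcript_id, skipped",
                path, rec.seqid, rec.start, rec.end,
            )
            continue
        tid = tids[0]
        chrom = rename.get(rec.seqid, rec.seqid) if rename else rec.seqid
        iv = GenomicInterval(chrom, rec.start - 1, rec.end, rec.strand)
        if tid not in exons:
            order.append(tid)
        exons.setdefault(tid, []).append(iv)
        gid = rec.attributes.get("gene_id")
        genes.setdefault(tid, gid[0] if gid else tid)
    return [TranscriptModel(tid, genes[tid], exons[tid]) for tid in order]


def write_gtf(models: list[TranscriptModel], path) -> None:
    """Write transcript models back to GTF exon records (inverse of :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for m in models:
            for iv in m.intervals:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.id}";'
                fh.write(
                    f"{iv.chrom}\tlncsig\texon\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def splice_sequence(model: TranscriptModel, genome: dict[str, str]) -> TranscriptModel:
    """Extract the spliced sense-strand sequence of ``model`` from ``genome``.

    Exon substrings are concatenated in genomic order and the whole spliced
    sequence reverse-complemented for minus-strand models. Output is
    uppercase; an exon outside the chromosome bounds raises ``ValueError``
    naming the transcript.
    """
    if model.chrom not in genome:
        raise ValueError(f"{model.id}: chromosome {model.chrom!r} absent from genome")
    chrom_seq = genome[model.chrom]
    parts = []
    for iv in model.intervals:
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"{model.id}: exon [{iv.start},{iv.end}) beyond end of {iv.chrom} "
                f"(length {len(chrom_seq)})"
            )
        parts.append(chrom_seq[iv.start : iv.end])
    seq = "".join(parts).upper()
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return replace(model, sequence=seq)


def read_bedgraph(path, rename: dict[str, str] | None = None) -> ScoreTrack:
    """Read a 4-column bedGraph (0-based half-open) into a :class:`ScoreTrack`."""
    track = ScoreTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = rename.get(fields[0], fields[0]) if rename else fields[0]
            track.add(chrom, int(fields[1]), int(fields[2]), float(fields[3]))
    return track


def read_repeatmasker(
    path, family_map: dict[str, str], rename: dict[str, str] | None = None
) -> RepeatCatalog:
    """Read repeat annotations from RepeatMasker ``.out`` or labelled BED.

    The dialect is sniffed per file: tab-separated 4+-column records with an
    integer in columns 2-3 are treated as BED (0-based half-open, family in
    column 4); otherwise the whitespace table of RepeatMasker ``.out``
    (three header lines, 1-based closed coordinates, repeat class/family in
    column 11) is assumed. ``family_map`` translates the raw family label
    (e.g. ``SINE/Alu``) to the configured feature vocabulary (``SINE.Alu``);
    records with unmapped families are dropped and counted.
    """
    catalog = RepeatCatalog()
    with open(path) as fh:
        lines = fh.readlines()
    is_bed = bool(lines) and "\t" in lines[0] and not lines[0].lower().startswith("track")
    if is_bed:
        records = []
        for lineno, line in enumerate(lines, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            try:
                records.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable BED record") from exc
    else:
        records = []
        for lineno, line in enumerate(lines, 1):
            fields = line.split()
            if not fields or not fields[0].replace(".", "").isdigit():
                continue  # header / blank lines
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: truncated RepeatMasker record")
            try:
                # columns: SWscore, div, del, ins, query, qbegin, qend, ...
                records.append((fields[4], int(fields[5]) - 1, int(fields[6]), fields[10]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable RepeatMasker record") from exc
    for chrom, start, end, raw_family in records:
        fam = family_map.get(raw_family)
        if fam is None:
            catalog.dropped += 1
            continue
        if rename:
            chrom = rename.get(chrom, chrom)
        catalog.entries.append((GenomicInterval(chrom, start, end), fam))
    catalog.entries.sort(key=lambda e: (e[0].chrom, e[0].start, e[0].end, e[1]))
    return catalog


def write_feature_table(table: "pd.DataFrame | object", path) -> None:
    """Serialize a feature table to TSV: id column first, ``label`` last when present.

    Missing feature values are written as ``NA``.
    """
    from lncsig.features import FeatureTable

    if isinstance(table, FeatureTable):
        df = table.to_frame()
    else:
        df = table
    if df.index.duplicated().any():
        raise ValueError("duplicate transcript ids")
    cols = [c for c in df.columns if c != "label"] + (
        ["label"] if "label" in df.columns else []
    )
    df[cols].to_csv(path, sep="\t", index_label="transcript_id", na_rep="NA")


def read_feature_table(path):
    """Read a TSV written by :func:`write_feature_table` back into a FeatureTable."""
    from lncsig.features import FeatureTable

    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    if df.index.duplicated().any():
        raise ValueError("duplicate transcript ids")
    return FeatureTable.from_frame(df)
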