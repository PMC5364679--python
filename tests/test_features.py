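"""Feature extraction: ORF search vs brute force, Fickett dual implementation,
k-mer counting identities, conservation aggregation, repeat-overlap bitmap oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncsig.features import (
    DINUCLEOTIDES,
    TRINUCLEOTIDES,
    FeatureConfig,
    KozakMatrix,
    basic_features,
    build_feature_table,
    conservation_features,
    fickett_position_parameter,
    fickett_score,
    find_orf,
    kmer_frequencies,
    orf_features,
    repeat_features,
)
from lncsig.transcript_io import (
    GenomicInterval,
    RepeatCatalog,
    ScoreTrack,
    TranscriptModel,
)

STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(seq: str, allow_open: bool):
    """Exhaustive enumeration of all ATG->(first in-frame stop) candidates."""
    seq = seq.upper()
    L = len(seq)
    stopped, opened = [], []
    for i in range(L - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        hit = None
        while j + 3 <= L:
            if j > i and seq[j : j + 3] in STOPS:
                hit = j + 3
                break
            j += 3
        if hit is not None:
            stopped.append((i, hit))
        else:
            opened.append((i, i + 3 * ((L - i) // 3)))
    pool = stopped if stopped else (opened if allow_open else [])
    if not pool:
        return None
    return max(pool, key=lambda c: (c[1] - c[0], -c[0]))


def seq_from_int(value: int, length: int) -> str:
    return "".join("ACGT"[(value >> (2 * i)) & 3] for i in range(length))


class TestFindOrf:
    def test_single_candidate(self):
        orf = find_orf("ATGAAATAG")
        assert (orf.start, orf.end, orf.has_stop) == (0, 9, True)

    def test_no_start_codon(self):
        assert find_orf("CCCCCC") is None

    def test_open_ended_fallback_truncates_to_codons(self):
        orf = find_orf("CCATGAAAA", allow_open=True)
        assert (orf.start, orf.end, orf.has_stop) == (2, 8, False)
        assert find_orf("CCATGAAAA", allow_open=False) is None

    def test_stopped_candidate_preferred_over_longer_open_run(self):
        # frame 0: short stopped ORF; frame 1: long open run
        seq = "ATGTAACATGAAAAAAAAAAAA"
        orf = find_orf(seq, allow_open=True)
        assert orf.has_stop

    @pytest.mark.parametrize("allow_open", [True, False])
    def test_exhaustive_small_sequences(self, allow_open):
        for L in range(3, 8):
            for v in range(4**L):
                seq = seq_from_int(v, L)
                got = find_orf(seq, allow_open=allow_open)
                want = orf_oracle(seq, allow_open=allow_open)
                got_t = None if got is None else (got.start, got.end)
                assert got_t == want, seq

    def test_random_long_sequences_match_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
            got = find_orf(seq)
            want = orf_oracle(seq, allow_open=True)
            assert (None if got is None else (got.start, got.end)) == want

    def test_n_codons_are_inert(self):
        assert find_orf("NNATGNNNTAGNN", allow_open=False).end == 11
        assert find_orf("ATNGAA", allow_open=True) is None


class TestBasicAndOrfFeatures:
    def _model(self, exon_lens, seq=None):
        ivs, pos = [], 0
        for ln in exon_lens:
            ivs.append(GenomicInterval("c", pos, pos + ln))
            pos += ln + 10
        return TranscriptModel("t", "g", ivs, sequence=seq)

    @pytest.mark.parametrize(
        "lens,expected",
        [([100, 200], (2, 300, 150)), ([7], (1, 7, 7)), ([10, 10, 10], (3, 30, 10))],
    )
    def test_basic_features(self, lens, expected):
        feats = basic_features(self._model(lens))
        assert (feats["TxNex"], feats["TxLen"], feats["TxExLenAvg"]) == expected

    def test_orf_proportion(self):
        seq = "ATGAAATAG" + "C" * 21
        m = self._model([30], seq)
        feats = orf_features(m, find_orf(seq), KozakMatrix.uniform())
        assert feats["OrfLen"] == 9 and feats["OrfProp"] == pytest.approx(0.3)

    def test_no_orf_zeroes_all(self):
        m = self._model([6], "CCCCCC")
        feats = orf_features(m, None, KozakMatrix.uniform())
        assert feats == {"OrfLen": 0.0, "OrfProp": 0.0, "KOZAK": 0.0}

    def test_uniform_matrix_score_is_window_times_weight(self):
        m = self._model([30], "ATGAAATAG" + "C" * 21)
        mat = KozakMatrix.uniform(weight=0.5)
        feats = orf_features(m, find_orf(m.sequence), mat)
        assert feats["KOZAK"] == pytest.approx(mat.window * 0.5)

    def test_consensus_context_beats_anti_consensus(self):
        mat = KozakMatrix.default()
        consensus = "GCCACC" + "ATG" + "G"
        anti = "ATTTTT" + "ATG" + "T"
        assert mat.score(consensus, 6) > mat.score(anti, 6)

    def test_out_of_window_positions_use_neutral_weight(self):
        mat = KozakMatrix.default()
        # ORF at position 0: all upstream offsets fall outside the sequence
        short = mat.score("ATGG", 0)
        padded = mat.score("NNNNNN" + "ATGG", 6)  # N also scores neutral
        assert short == pytest.approx(padded)


def fickett_oracle(seq: str) -> float:
    """Independent TESTCODE implementation (np.digitize lookup)."""
    pos_prob = {
        "A": [0.22, 0.20, 0.34, 0.45, 0.68, 0.58, 0.93, 0.84, 0.68, 0.94],
        "C": [0.23, 0.30, 0.33, 0.51, 0.48, 0.66, 0.81, 0.70, 0.70, 0.80],
        "G": [0.08, 0.08, 0.16, 0.27, 0.48, 0.53, 0.64, 0.74, 0.88, 0.90],
        "T": [0.09, 0.09, 0.20, 0.54, 0.44, 0.69, 0.68, 0.91, 0.97, 0.97],
    }
    cont_prob = {
        "A": [0.21, 0.81, 0.65, 0.67, 0.49, 0.62, 0.55, 0.44, 0.49, 0.28],
        "C": [0.31, 0.39, 0.44, 0.43, 0.59, 0.59, 0.64, 0.51, 0.64, 0.82],
        "G": [0.29, 0.33, 0.41, 0.41, 0.73, 0.64, 0.64, 0.47, 0.54, 0.40],
        "T": [0.58, 0.51, 0.69, 0.56, 0.75, 0.55, 0.40, 0.39, 0.24, 0.28],
    }
    pos_w = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
    cont_w = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
    pos_edges = [1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9]
    cont_edges = [0.17, 0.19, 0.21, 0.23, 0.25, 0.27, 0.29, 0.31, 0.33]
    total = 0.0
    for b in "ACGT":
        counts = [seq[p::3].count(b) for p in range(3)]
        pos_param = max(counts) / (min(counts) + 1.0)
        total += pos_prob[b][int(np.digitize(pos_param, pos_edges, right=False))] * pos_w[b]
        content = seq.count(b) / len(seq)
        total += cont_prob[b][int(np.digitize(content, cont_edges, right=False))] * cont_w[b]
    return total


class TestFickett:
    def test_position_parameter_formula(self):
        assert fickett_position_parameter("AAAAAAAAA", "A") == pytest.approx(3 / 4)

    def test_matches_independent_oracle_on_fixture(self):
        seq = "ATGGCATCGATCGATAACCGGTTAACCGGTTATATATCGCGCGATCGATCGTAGCTAGCT"
        assert len(seq) == 60
        assert fickett_score(seq) == pytest.approx(fickett_oracle(seq))

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            L = int(rng.integers(30, 400))
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
            assert fickett_score(seq) == pytest.approx(fickett_oracle(seq)), seq

    def test_equal_table_bins_give_equal_score(self):
        # appending one codon that leaves every phase count max/min and every
        # composition inside the same lookup bins leaves the score unchanged
        seq = "ACGT" * 30
        assert fickett_score(seq) == pytest.approx(fickett_score(seq + "ACGTACGT"))


class TestKmerFrequencies:
    def test_acgt_example(self):
        f = kmer_frequencies("ACGT")
        assert f["AC"] == f["CG"] == f["GT"] == 0.25
        assert f["ACG"] == f["CGT"] == 0.25
        assert sum(f.values()) == pytest.approx(0.25 * 5)

    def test_homopolymer_counts(self):
        f = kmer_frequencies("AAAA")
        assert f["AA"] == pytest.approx(3 / 4)
        assert f["AAA"] == pytest.approx(2 / 4)

    @settings(max_examples=25, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=400))
    def test_counting_identity(self, seq):
        f = kmer_frequencies(seq)
        L = len(seq)
        di = sum(f[k] for k in DINUCLEOTIDES)
        tri = sum(f[k] for k in TRINUCLEOTIDES)
        assert di == pytest.approx((L - 1) / L)
        assert tri == pytest.approx((L - 2) / L)

    def test_windows_with_n_skipped(self):
        f = kmer_frequencies("AANAA")
        assert f["AA"] == pytest.approx(2 / 5)
        assert sum(f[k] for k in TRINUCLEOTIDES) == 0.0


class TestConservationFeatures:
    def _model_two_exons(self):
        return TranscriptModel("t", "g", [
            GenomicInterval("c", 0, 10), GenomicInterval("c", 20, 30)
        ])

    def test_flat_exon_scores(self):
        track = ScoreTrack()
        track.add("c", 0, 10, 0.2)
        track.add("c", 20, 30, 0.8)
        feats = conservation_features(self._model_two_exons(), track, "ph8")
        assert feats == pytest.approx({"ph8m": 0.5, "ph8mx": 0.8, "ph8mn": 0.2})

    def test_single_exon_degenerate(self):
        m = TranscriptModel("t", "g", [GenomicInterval("c", 0, 10)])
        track = ScoreTrack()
        track.add("c", 0, 10, 0.4)
        feats = conservation_features(m, track, "x")
        assert feats["xm"] == feats["xmx"] == feats["xmn"] == pytest.approx(0.4)

    def test_unweighted_exon_means(self):
        # exon means (0.5, 0.5) despite very different exon lengths
        m = TranscriptModel("t", "g", [
            GenomicInterval("c", 0, 4), GenomicInterval("c", 10, 11)
        ])
        track = ScoreTrack()
        for pos, v in zip(range(4), [0.0, 1.0, 1.0, 0.0]):
            track.add("c", pos, pos + 1, v)
        track.add("c", 10, 11, 0.5)
        feats = conservation_features(m, track, "p")
        assert feats == pytest.approx({"pm": 0.5, "pmx": 0.5, "pmn": 0.5})

    def test_undefined_exons_excluded_and_all_undefined_is_missing(self):
        track = ScoreTrack()
        track.add("c", 0, 10, 0.3)
        feats = conservation_features(self._model_two_exons(), track, "p")
        assert feats["pm"] == pytest.approx(0.3)
        empty = conservation_features(self._model_two_exons(), ScoreTrack(), "p")
        assert all(np.isnan(v) for v in empty.values())


class TestRepeatFeatures:
    def test_whole_exon_coverage(self):
        m = TranscriptModel("t", "g", [
            GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)
        ])
        cat = RepeatCatalog(entries=[(GenomicInterval("c", 0, 100), "SINE.Alu")])
        feats = repeat_features(m, cat, ["SINE.Alu", "LINE.L1"])
        assert feats == {"SINE.Alu": 0.5, "LINE.L1": 0.0}

    def test_duplicate_intervals_union_semantics(self):
        m = TranscriptModel("t", "g", [GenomicInterval("c", 0, 100)])
        iv = GenomicInterval("c", 10, 60)
        one = repeat_features(m, RepeatCatalog(entries=[(iv, "F")]), ["F"])
        two = repeat_features(m, RepeatCatalog(entries=[(iv, "F"), (iv, "F")]), ["F"])
        assert one == two == {"F": 0.5}

    def test_random_catalog_matches_bitmap_oracle(self):
        rng = np.random.default_rng(4)
        exons = [GenomicInterval("c", 0, 150), GenomicInterval("c", 200, 400),
                 GenomicInterval("c", 500, 550)]
        m = TranscriptModel("t", "g", exons)
        families = ["A", "B", "C"]
        entries = []
        for _ in range(20):
            s = int(rng.integers(0, 580))
            e = s + int(rng.integers(10, 120))
            entries.append((GenomicInterval("c", s, e), families[rng.integers(0, 3)]))
        cat = RepeatCatalog(entries=entries)
        got = repeat_features(m, cat, families)
        # per-base bitmap oracle
        for fam in families:
            bitmap = np.zeros(1000, dtype=bool)
            for iv, f in entries:
                if f == fam:
                    bitmap[iv.start : iv.end] = True
            covered = sum(int(bitmap[iv.start : iv.end].sum()) for iv in exons)
            assert got[fam] == pytest.approx(covered / m.length)


class TestBuildFeatureTable:
    def test_column_count_arithmetic(self, small_sim):
        models = small_sim.models[:6]
        table = build_feature_table(
            models, tracks=small_sim.tracks, catalog=small_sim.catalog,
            config=FeatureConfig(repeat_families=["SINE.Alu", "LINE.L1"]),
        )
        assert table.p == 3 + 3 + 3 + 81 + 2

    def test_missing_context_drops_blocks(self, small_sim):
        table = build_feature_table(small_sim.models[:4])
        assert table.p == 3 + 3 + 81
        assert not any("." in c or c.startswith("ph8") for c in table.feature_names)

    def test_input_order_invariance(self, small_sim):
        models = small_sim.models[:8]
        a = build_feature_table(models, tracks=small_sim.tracks,
                                catalog=small_sim.catalog)
        b = build_feature_table(models[::-1], tracks=small_sim.tracks,
                                catalog=small_sim.catalog)
        assert a.feature_names == b.feature_names
        assert a.values.sort_index().equals(b.values.sort_index())

    def test_bounded_feature_ranges(self, small_sim):
        table = build_feature_table(
            small_sim.models, tracks=small_sim.tracks, catalog=small_sim.catalog
        )
        vals = table.values
        kmers = vals[DINUCLEOTIDES + TRINUCLEOTIDES]
        assert ((kmers >= 0) & (kmers <= 1)).all().all()
        assert ((vals["OrfProp"] >= 0) & (vals["OrfProp"] <= 1)).all()
        assert (vals["OrfLen"] <= vals["TxLen"]).all()
        assert np.allclose(vals["OrfProp"] * vals["TxLen"], vals["OrfLen"])
        reps = vals[[c for c in table.feature_names if "." in c]]
        assert ((reps >= 0) & (reps <= 1)).all().all()
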