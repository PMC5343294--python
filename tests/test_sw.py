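import numpy as np
import pytest
from Bio import Align

from bibs.cal import CAL
from bibs.fmindex import encode
from bibs.search import Seed
from bibs.sw import (
    Alignment,
    ScoringScheme,
    align_read_in_window,
    fill_and_assemble,
    pick_best,
    smith_waterman,
)

BASES = "ACGT"


def rand_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def oracle_local_score(ref, query, match, mismatch, gap):
    """Independent full-matrix local DP (linear gaps) for score checks."""
    n, m = len(ref), len(query)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == query[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap,
                          H[i][j - 1] + gap)
            best = max(best, H[i][j])
    return best


class TestScoringScheme:
    def test_defaults_valid(self):
        s = ScoringScheme()
        assert s.match > 0 and s.mismatch < 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"match": 0},
            {"mismatch": 1},
            {"gap_open": 1},
            {"gap_open": -1, "gap_extend": -2},
        ],
    )
    def test_invalid_schemes(self, kwargs):
        with pytest.raises(ValueError):
            ScoringScheme(**kwargs)


class TestSmithWaterman:
    def test_identical_segments(self):
        scheme = ScoringScheme(match=2, mismatch=-3, gap_open=-5, gap_extend=-2)
        for n in (1, 5, 20):
            seg = "ACGT" * 5
            score, path = smith_waterman(seg[:n], seg[:n], scheme)
            assert score == 2 * n
            assert path[4] == [("M", n)]

    def test_empty_read_segment(self):
        assert smith_waterman("ACGT", "", ScoringScheme())[0] == 0

    def test_linear_gap_example_matches_oracle(self):
        ref, query = "TGTTACGG", "GGTTGACTA"
        scheme = ScoringScheme(match=3, mismatch=-3, gap_open=-2, gap_extend=-2)
        expected = oracle_local_score(ref, query, 3, -3, -2)
        score, _ = smith_waterman(ref, query, scheme)
        assert score == expected

    def test_random_pairs_match_biopython(self, rng):
        """Affine-gap scores agree with Bio.Align.PairwiseAligner in
        local mode on random segment pairs."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 5
        aligner.mismatch_score = -4
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
        scheme = ScoringScheme(5, -4, -10, -1)
        for _ in range(50):
            ref = rand_seq(rng, int(rng.integers(5, 60)))
            query = rand_seq(rng, int(rng.integers(5, 60)))
            score, _ = smith_waterman(ref, query, scheme)
            expected = int(aligner.score(ref, query)) if score else 0
            if score > 0:
                assert score == expected

    def test_banded_equals_full(self, rng):
        """Banded DP (band = segment length + 2 x pad) reproduces the
        full matrix exactly on 500 random pairs."""
        scheme = ScoringScheme()
        for _ in range(500):
            n = int(rng.integers(1, 65))
            m = int(rng.integers(1, 65))
            ref = rand_seq(rng, n)
            query = rand_seq(rng, m)
            band = max(n, m) + 16
            full_score, full_path = smith_waterman(ref, query, scheme, band=-1)
            band_score, band_path = smith_waterman(ref, query, scheme, band=band)
            assert band_score == full_score
            assert band_path == full_path

    def test_banded_storage_kernel_matches_full(self, rng):
        """The banded-storage kernel path (band narrower than the
        matrix) gives the same near-diagonal alignments."""
        scheme = ScoringScheme()
        for _ in range(50):
            m = int(rng.integers(40, 80))
            query = rand_seq(rng, m)
            ref = list(query)
            ref[m // 2] = BASES[(BASES.index(ref[m // 2]) + 1) % 4]
            ref = "".join(ref)
            full_score, _ = smith_waterman(ref, query, scheme, band=-1)
            band_score, _ = smith_waterman(ref, query, scheme, band=10)
            assert band_score == full_score


def mk_cal(members, strand="+"):
    positions = [p for _, p in members]
    lo = min(p - s.read_start for s, p in members)
    return CAL(lo - 10, lo + 180, strand, sorted(members, key=lambda m: m[0].read_start))


def seed_at(read_start, read_end, pos, edits=(), span=None, eids=0):
    return (
        Seed(
            read_start=read_start,
            read_end=read_end,
            direction="forward",
            genome_starts=np.array([pos], dtype=np.int64),
            n_occurrences=1,
            eids_used=eids,
            edits=tuple(edits),
            genome_span=span if span is not None else read_end - read_start,
        ),
        pos,
    )


class TestFillAndAssemble:
    def test_unmutated_read_full_match(self, rng):
        text = rand_seq(rng, 1000)
        read = text[300:450]
        pattern = encode(read)
        cal = mk_cal([seed_at(0, 70, 300), seed_at(70, 150, 370)])
        aln = fill_and_assemble(cal, pattern, encode(text))
        assert aln is not None
        assert aln.position == 300
        assert aln.cigar == "150M"
        assert aln.edit_distance == 0

    def test_two_nt_deletion_between_seeds(self, rng):
        text = rand_seq(rng, 1000)
        # read = genome with 2 nt missing between the seeds
        read = text[300:370] + text[372:452]
        pattern = encode(read)
        cal = mk_cal([seed_at(0, 70, 300), seed_at(70, 150, 372)])
        aln = fill_and_assemble(cal, pattern, encode(text))
        assert aln is not None
        assert "2D" in aln.cigar
        assert aln.position == 300

    def test_unrelated_window_rejected(self, rng):
        text = rand_seq(rng, 1000)
        read = rand_seq(rng, 150)  # unrelated to the window
        pattern = encode(read)
        cal = mk_cal([seed_at(0, 20, 300), seed_at(130, 150, 430)])
        aln = fill_and_assemble(cal, pattern, encode(text))
        assert aln is None  # identity filter

    def test_cigar_consumes_read_with_random_edits(self, rng):
        """Assembled CIGARs consume exactly the read length for reads
        carrying 0-3 random substitutions between two anchor seeds."""
        text = rand_seq(rng, 5000)
        for _ in range(25):
            start = int(rng.integers(0, 4500))
            read = list(text[start:start + 200])
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.integers(60, 140))
                read[pos] = BASES[(BASES.index(read[pos]) + 1) % 4]
            pattern = encode("".join(read))
            cal = CAL(start - 10, start + 210, "+",
                      [seed_at(0, 60, start),
                       seed_at(140, 200, start + 140)])
            aln = fill_and_assemble(cal, pattern, encode(text))
            assert aln is not None
            consumed = sum(
                int(n) for n, op in
                __import__("re").findall(r"(\d+)([MIS])", aln.cigar)
            )
            assert consumed == 200

    def test_score_additivity(self, rng):
        """The assembled score is at least the sum of the gap scores:
        seed blocks contribute non-negatively."""
        text = rand_seq(rng, 2000)
        read = list(text[500:700])
        read[100] = BASES[(BASES.index(read[100]) + 1) % 4]
        pattern = encode("".join(read))
        scheme = ScoringScheme()
        cal = CAL(490, 710, "+",
                  [seed_at(0, 90, 500), seed_at(110, 200, 610)])
        aln = fill_and_assemble(cal, pattern, encode(text), scheme)
        gap_score, _ = smith_waterman(text[590:610], "".join(read[90:110]), scheme)
        assert aln.score >= gap_score


def test_align_read_in_window(rng):
    text = rand_seq(rng, 800)
    read = list(text[200:350])
    read[75] = BASES[(BASES.index(read[75]) + 1) % 4]
    aln = align_read_in_window(encode("".join(read)), encode(text), 196, 354, "+")
    assert aln.position == 200
    assert aln.cigar == "150M"
    assert aln.edit_distance == 1


class TestPickBest:
    def mk(self, score, nm, pos):
        return Alignment(position=pos, strand="+", cigar="10M",
                         score=score, edit_distance=nm)

    def test_single_candidate_mapq60(self):
        a = self.mk(100, 0, 5)
        best, mapq = pick_best([a])
        assert best is a and mapq == 60

    def test_exact_tie_mapq0_leftmost(self):
        a, b = self.mk(80, 2, 900), self.mk(80, 2, 100)
        best, mapq = pick_best([a, b])
        assert best.position == 100 and mapq == 0

    def test_score_gap_mapq(self):
        a, b = self.mk(100, 0, 5), self.mk(80, 3, 50)
        best, mapq = pick_best([a, b])
        assert best is a
        assert mapq == min(60, round(0.4 * 20))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pick_best([])
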