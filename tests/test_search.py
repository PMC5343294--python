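import re

import edlib
import numpy as np
import pytest

from bibs.fmindex import build_fm_index, encode
from bibs.search import (
    SearchBudget,
    backward_extend,
    bidirectional_align,
    forward_extend,
    iterative_seed,
)

BASES = "ACGT"


def rand_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


@pytest.fixture(scope="module")
def toy():
    text = "GATTACA"
    return build_fm_index(text), build_fm_index(text[::-1]), text


class TestSearchBudget:
    def test_valid_budgets(self):
        assert SearchBudget(2).backward == 1 and SearchBudget(2).forward == 1
        assert SearchBudget(1).backward == 1 and SearchBudget(1).forward == 0
        assert SearchBudget(2, split=(2, 0)).backward == 2

    def test_invalid(self):
        with pytest.raises(ValueError):
            SearchBudget(3)
        with pytest.raises(ValueError):
            SearchBudget(2, split=(2, 1))


class TestBackwardExtend:
    def test_exact_suffix(self, toy):
        fm, _, _ = toy
        seed, _ = backward_extend(fm, encode("ACA"), 0, 3, 0)
        assert (seed.read_start, seed.read_end) == (0, 3)
        assert seed.genome_starts.tolist() == [4]

    def test_one_substitution(self, toy):
        fm, _, _ = toy
        seed, _ = backward_extend(fm, encode("AGA"), 0, 3, 1)
        assert (seed.read_start, seed.read_end) == (0, 3)
        assert seed.genome_starts.tolist() == [4]
        assert seed.eids_used == 1
        assert seed.edits == ((1, "X", 2),)  # C substituted at read pos 1

    def test_absent_symbol_budget0(self):
        fm = build_fm_index("AAAA")
        seed, _ = backward_extend(fm, encode("G"), 0, 1, 0)
        assert seed is None

    def test_n_in_read_never_matches(self):
        fm = build_fm_index("ANA")
        seed, _ = backward_extend(fm, encode("N"), 0, 1, 0)
        assert seed is None  # even though the genome contains N


class TestForwardExtend:
    def test_exact_prefix(self, toy):
        _, fmr, _ = toy
        seed, _ = forward_extend(fmr, encode("GAT"), 0, 3, 0)
        assert (seed.read_start, seed.read_end) == (0, 3)
        assert seed.genome_starts.tolist() == [0]

    def test_mirror_identity(self, rng):
        """forward extension == mirrored backward extension on the
        reversed genome and reversed read."""
        text = rand_seq(rng, 2000)
        fm_rev = build_fm_index(text[::-1])
        fm_on_rev_text = fm_rev
        for _ in range(30):
            read = rand_seq(rng, 30)
            f, _ = forward_extend(fm_rev, encode(read), 0, 30, 0)
            b, _ = backward_extend(fm_on_rev_text, encode(read[::-1]), 0, 30, 0)
            if f is None:
                assert b is None
                continue
            assert f.length == b.length
            mirrored = sorted(len(text) - p - b.genome_span
                              for p in b.genome_starts.tolist())
            assert sorted(f.genome_starts.tolist()) == mirrored

    def test_first_symbol_absent(self):
        fm_rev = build_fm_index("AAAA")
        seed, _ = forward_extend(fm_rev, encode("G"), 0, 1, 0)
        assert seed is None


def _index_pair(text):
    return build_fm_index(text), build_fm_index(text[::-1])


class TestBidirectional:
    def test_exact_read_fully_aligned(self, rng):
        text = rand_seq(rng, 5000)
        fwd, rev = _index_pair(text)
        read = text[1200:1300]
        res = bidirectional_align(fwd, rev, encode(read), SearchBudget(0))
        assert res.status == "fully_aligned"
        assert 1200 in res.full_hits.tolist()

    def test_substitution_near_each_end(self, rng):
        text = rand_seq(rng, 5000)
        fwd, rev = _index_pair(text)
        read = list(text[2000:2100])
        for pos in (5, 93):
            read[pos] = BASES[(BASES.index(read[pos]) + 1) % 4]
        res = bidirectional_align(fwd, rev, encode("".join(read)),
                                  SearchBudget(2))
        assert res.status == "fully_aligned"
        assert 2000 in res.full_hits.tolist()

    def test_center_cluster_yields_bracketing_seeds(self, rng):
        text = rand_seq(rng, 5000)
        fwd, rev = _index_pair(text)
        read = list(text[3000:3100])
        for pos in (49, 50, 51):
            read[pos] = BASES[(BASES.index(read[pos]) + 1) % 4]
        res = bidirectional_align(fwd, rev, encode("".join(read)),
                                  SearchBudget(2))
        assert res.status == "seeded"
        inner_lo, inner_hi = res.inner_limits
        # seeds must not cross the mutated cluster
        assert inner_lo <= 51 and inner_hi >= 50
        for s in res.seeds:
            if s.direction == "forward":
                assert s.read_end <= 50 + 2  # may stop within the cluster
            else:
                assert s.read_start >= 49

    def test_budget0_equals_exact_substring(self, rng):
        """On 500 random reads, budget-0 full alignment iff the read is
        an exact substring of the genome."""
        text = rand_seq(rng, 10_000)
        fwd, rev = _index_pair(text)
        n_present = 0
        for _ in range(500):
            if rng.random() < 0.5:
                start = int(rng.integers(0, 10_000 - 40))
                read = text[start:start + 40]
            else:
                read = rand_seq(rng, 40)
            res = bidirectional_align(fwd, rev, encode(read), SearchBudget(0))
            expected = [m.start() for m in re.finditer(f"(?={read})", text)]
            if expected:
                n_present += 1
                assert res.status == "fully_aligned"
                assert sorted(res.full_hits.tolist()) == expected
            else:
                assert res.status != "fully_aligned"
        assert n_present > 100  # the comparison actually exercised both cases


class TestIterativeSeed:
    def test_unmutated_read_one_iteration(self, rng):
        text = rand_seq(rng, 5000)
        fwd, rev = _index_pair(text)
        res = iterative_seed(fwd, rev, encode(text[100:400]), SearchBudget(0))
        assert res.status == "fully_aligned"

    def test_two_substitutions_partition_coverage(self, rng):
        """A 300 nt read mutated at ~100 and ~200 under budget 0 yields
        seeds jointly covering every clean partition of the read."""
        text = rand_seq(rng, 50_000)
        fwd, rev = _index_pair(text)
        read = list(text[10_000:10_300])
        for pos in (100, 200):
            read[pos] = BASES[(BASES.index(read[pos]) + 1) % 4]
        res = iterative_seed(fwd, rev, encode("".join(read)), SearchBudget(0))
        assert res.status == "seeded"
        assert max(s.iteration for s in res.seeds) == 2
        assert 3 <= len(res.seeds) <= 4
        covered = np.zeros(300, dtype=bool)
        for s in res.seeds:
            covered[s.read_start:s.read_end] = True
        clean = np.ones(300, dtype=bool)
        clean[[100, 200]] = False
        # every base except the mutated points (and the one-base shrink
        # around failure symbols) is covered by some seed
        assert (covered | ~clean).sum() >= 298

    def test_nested_iteration_intervals(self, rng):
        text = rand_seq(rng, 50_000)
        fwd, rev = _index_pair(text)
        read = list(text[20_000:20_300])
        for pos in (80, 150, 220):
            read[pos] = BASES[(BASES.index(read[pos]) + 1) % 4]
        res = iterative_seed(fwd, rev, encode("".join(read)), SearchBudget(0))
        by_iter = {}
        for s in res.seeds:
            by_iter.setdefault(s.iteration, []).append(s)
        iters = sorted(by_iter)
        for a, b in zip(iters, iters[1:]):
            lo_a = min(s.read_start for s in by_iter[a])
            hi_a = max(s.read_end for s in by_iter[a])
            for s in by_iter[b]:
                assert lo_a < s.read_start and s.read_end < hi_a

    def test_short_read_stops_after_one_iteration(self, rng):
        text = rand_seq(rng, 5000)
        fwd, rev = _index_pair(text)
        read = list(text[1000:1020])
        read[10] = BASES[(BASES.index(read[10]) + 1) % 4]
        res = iterative_seed(fwd, rev, encode("".join(read)), SearchBudget(0),
                             min_inner_len=15)
        assert all(s.iteration == 1 for s in res.seeds)


@pytest.fixture(scope="module")
def budget_setup():
    rng = np.random.default_rng(777)
    text = rand_seq(rng, 20_000)
    fwd, rev = _index_pair(text)
    reads = []
    for _ in range(120):
        start = int(rng.integers(0, 20_000 - 80))
        read = list(text[start:start + 80])
        for _ in range(int(rng.integers(0, 3))):
            pos = int(rng.integers(0, 80))
            read[pos] = BASES[(BASES.index(read[pos]) + 1) % 4]
        reads.append("".join(read))
    return text, fwd, rev, reads


class TestBudgetProperties:

    def test_monotone_in_budget(self, budget_setup):
        """Reads fully aligned at budget b stay fully aligned at b+1."""
        _, fwd, rev, reads = budget_setup
        full = {b: set() for b in (0, 1, 2)}
        for b in (0, 1, 2):
            for i, read in enumerate(reads):
                res = bidirectional_align(fwd, rev, encode(read), SearchBudget(b))
                if res.status == "fully_aligned":
                    full[b].add(i)
        assert full[0] <= full[1] <= full[2]
        assert len(full[2]) > len(full[0])  # the budget does something

    def test_seed_soundness(self, budget_setup):
        """Every reported seed placement is within eids_used edits of
        the read segment it covers (edlib as independent oracle)."""
        text, fwd, rev, reads = budget_setup
        rng = np.random.default_rng(3)
        dense = []
        for _ in range(40):
            start = int(rng.integers(0, 20_000 - 120))
            read = list(text[start:start + 120])
            for pos in (20, 50, 80, 105):
                read[pos] = BASES[(BASES.index(read[pos]) + 1) % 4]
            dense.append("".join(read))
        checked = 0
        for read in dense:
            res = iterative_seed(fwd, rev, encode(read), SearchBudget(2))
            for s in res.seeds:
                seg = read[s.read_start:s.read_end]
                for p in s.genome_starts.tolist()[:5]:
                    ref = text[p:p + s.genome_span]
                    d = edlib.align(seg, ref, task="distance")["editDistance"]
                    assert d <= s.eids_used
                    checked += 1
        assert checked > 50

    def test_bidirectional_search_tree_not_larger_than_unidirectional(self, budget_setup):
        """A 1+1 budget split expands no more FM intervals than a
        unidirectional budget-2 search over the same reads."""
        _, fwd, rev, reads = budget_setup
        bidi = uni = 0
        for read in reads:
            pattern = encode(read)
            res = bidirectional_align(fwd, rev, pattern, SearchBudget(2))
            bidi += res.expansions
            _, exp = backward_extend(fwd, pattern, 0, len(read), 2)
            uni += exp
        assert bidi <= uni
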