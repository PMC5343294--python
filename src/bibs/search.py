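"""EID-bounded unidirectional and bidirectional FM-index search.

An EID is one unit edit tolerated during search: a substitution, an
inserted read base, or a deleted read base. Extension proceeds exactly
until the occurrence interval would become empty; at that failure point
the search branches — substitution first, then deletion, then
insertion — while budget remains. Splitting a budget of two as one per
direction lets the two extensions jointly tolerate two edits without
the multiplicative search-tree growth a unidirectional two-EID search
incurs.

All functions here are strand-agnostic: they operate on an encoded
pattern and a (forward-text, reversed-text) FM-index pair. The
bisulfite layer chooses which converted pattern meets which index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bibs.fmindex import FMIndex

#: occurrence-interval size above which a seed is flagged low-specificity
OCC_CAP = 500


@dataclass(frozen=True)
class SearchBudget:
    """Edit budget for one bidirectional search.

    ``max_eids`` is the total (0, 1 or 2); ``split`` divides it between
    the backward and forward extensions. The default split gives each
    direction half of an even budget; an odd budget favours the
    backward (read-end) direction.
    """

    max_eids: int = 2
    split: tuple[int, int] | None = None  # (backward, forward); None = auto

    def __post_init__(self) -> None:
        if self.max_eids not in (0, 1, 2):
            raise ValueError("max_eids must be 0, 1 or 2")
        if self.split is not None:
            b, f = self.split
            if b < 0 or f < 0 or b + f != self.max_eids:
                raise ValueError(f"split {self.split} inconsistent with budget")

    @property
    def backward(self) -> int:
        if self.split is not None:
            return self.split[0]
        return (self.max_eids + 1) // 2

    @property
    def forward(self) -> int:
        if self.split is not None:
            return self.split[1]
        return self.max_eids // 2


@dataclass
class Seed:
    """A read sub-interval placed on the genome by BWT extension.

    ``read_start``/``read_end`` are 0-based half-open pattern
    coordinates. ``genome_starts`` hold up to :data:`OCC_CAP` global
    start positions of the matched genome segment; ``n_occurrences`` is
    the full interval size (``low_specificity`` when it exceeds the
    cap). ``edits`` record where budget was spent, as
    (read_offset, op, base) with op in {"X","I","D"}; for "D" the
    offset is the read boundary the extra genome base sits before.
    ``genome_span`` is the number of genome bases the seed consumes.
    """

    read_start: int
    read_end: int
    direction: str  # "forward" | "backward"
    genome_starts: np.ndarray
    n_occurrences: int
    eids_used: int
    iteration: int = 1
    edits: tuple = ()
    genome_span: int = 0

    @property
    def length(self) -> int:
        return self.read_end - self.read_start

    @property
    def low_specificity(self) -> bool:
        return self.n_occurrences > OCC_CAP


@dataclass
class SeedingResult:
    """Outcome of one bidirectional pass or the full iterative loop."""

    status: str  # "fully_aligned" | "seeded" | "unseeded"
    full_hits: np.ndarray | None = None  # global genome start positions
    full_eids: int = 0
    seeds: list[Seed] = field(default_factory=list)
    inner_limits: tuple[int, int] = (0, 0)
    expansions: int = 0  # FM-interval expansion counter (search-tree size)


#: how far back from a failure point an EID branch may be placed. Exact
#: extension overruns a true edit by the spurious-match length, about
#: log_sigma(genome) symbols; 16 covers genomes well beyond 1 Gb.
BACKTRACK_WINDOW = 16


class _Extender:
    """Shared DFS machinery for one direction of EID-bounded extension.

    Extension is exact until the occurrence interval empties; an EID
    branch (substitution, then deletion, then insertion) may then be
    placed at the failure symbol or at any matched symbol within
    :data:`BACKTRACK_WINDOW` of it, after which extension resumes
    exactly. Backtracking matters because the exact match can coast
    past a true edit on a chance occurrence elsewhere in the genome.
    """

    __slots__ = ("index", "seg", "budget", "candidates", "expansions")

    def __init__(self, index: FMIndex, seg: np.ndarray, budget: int):
        self.index = index
        self.seg = seg
        self.budget = budget
        self.candidates: list[tuple] = []
        self.expansions = 0

    def run(self) -> tuple | None:
        m = len(self.seg)
        self._dfs(m - 1, 0, self.index.size, 0, (), 0)
        best = None
        for cand in self.candidates:
            stop, lo, hi, eids, edits, glen = cand
            if stop == m:  # matched nothing
                continue
            if best is None or (stop, eids) < (best[0], best[3]):
                best = cand
        return best

    def _dfs(self, j: int, lo: int, hi: int, eids: int, edits: tuple, glen: int) -> None:
        m = len(self.seg)
        lo_hist = np.empty(j + 1, dtype=np.int64)
        hi_hist = np.empty(j + 1, dtype=np.int64)
        fail, lo2, hi2, steps = self.index.extend_exact_trace(
            self.seg, j, lo, hi, lo_hist, hi_hist
        )
        self.expansions += steps
        if fail == -1:
            self.candidates.append((0, lo2, hi2, eids, edits, glen + j + 1))
            return
        glen2 = glen + (j - fail)
        self.candidates.append((fail + 1, lo2, hi2, eids, edits, glen2))
        if eids >= self.budget:
            return
        # branch at the failure symbol and at recently matched symbols,
        # exploring substitutions first, then deletions, then insertions
        positions = []
        for jb in range(fail, min(j, fail + BACKTRACK_WINDOW) + 1):
            if jb == fail:
                blo, bhi = lo2, hi2
            else:
                t = j - jb - 1  # interval after matching symbol jb + 1
                if t < 0:
                    blo, bhi = lo, hi
                else:
                    blo, bhi = int(lo_hist[t]), int(hi_hist[t])
            positions.append((jb, blo, bhi, glen + (j - jb)))
        for jb, blo, bhi, bglen in positions:  # substitutions
            c_read = self.seg[jb]
            for c in (1, 2, 3, 4):
                if c == c_read:
                    continue
                l3, h3 = self.index.step(c, blo, bhi)
                self.expansions += 1
                if l3 < h3:
                    self._dfs(jb - 1, l3, h3, eids + 1,
                              edits + ((jb, "X", c),), bglen + 1)
        for jb, blo, bhi, bglen in positions:  # deletions (extra genome base)
            for c in (1, 2, 3, 4):
                l3, h3 = self.index.step(c, blo, bhi)
                self.expansions += 1
                if l3 < h3:
                    self._dfs(jb, l3, h3, eids + 1,
                              edits + ((jb + 1, "D", c),), bglen + 1)
        for jb, blo, bhi, bglen in positions:  # insertions (extra read base)
            self._dfs(jb - 1, blo, bhi, eids + 1,
                      edits + ((jb, "I", 0),), bglen)


def backward_extend(
    index: FMIndex,
    pattern: np.ndarray,
    start: int,
    end: int,
    budget: int,
    iteration: int = 1,
) -> tuple[Seed | None, int]:
    """Extend backwards from pattern position ``end`` down to ``start``.

    Returns the longest suffix-anchored seed over pattern[start:end)
    mapping with at most ``budget`` EIDs (None when not even one symbol
    can be placed), plus the FM-expansion count.
    """
    seg = pattern[start:end]
    ext = _Extender(index, seg, budget)
    best = ext.run()
    if best is None:
        return None, ext.expansions
    stop, lo, hi, eids, edits, glen = best
    n_occ = hi - lo
    starts = index.locate(lo, hi, cap=OCC_CAP)
    seed = Seed(
        read_start=start + stop,
        read_end=end,
        direction="backward",
        genome_starts=np.sort(starts),
        n_occurrences=n_occ,
        eids_used=eids,
        iteration=iteration,
        edits=tuple((start + o, op, b) for o, op, b in reversed(edits)),
        genome_span=glen,
    )
    return seed, ext.expansions


def forward_extend(
    index_rev: FMIndex,
    pattern: np.ndarray,
    start: int,
    end: int,
    budget: int,
    iteration: int = 1,
) -> tuple[Seed | None, int]:
    """Extend forwards from pattern position ``start`` up to ``end``.

    Implemented as backward extension of the reversed segment on the
    reversed-text index; genome positions are mirrored back.
    """
    seg = pattern[start:end][::-1].copy()
    ext = _Extender(index_rev, seg, budget)
    best = ext.run()
    if best is None:
        return None, ext.expansions
    stop, lo, hi, eids, edits, glen = best
    m = end - start
    n = index_rev.text_length
    n_occ = hi - lo
    rev_starts = index_rev.locate(lo, hi, cap=OCC_CAP)
    starts = n - rev_starts - glen  # mirror to forward-text coordinates
    # mirror edit offsets: reversed-segment offset o -> pattern offset
    mirrored = []
    for o, op, b in edits:
        if op == "D":
            mirrored.append((start + (m - o), "D", b))
        else:
            mirrored.append((start + (m - 1 - o), op, b))
    seed = Seed(
        read_start=start,
        read_end=start + (m - stop),
        direction="forward",
        genome_starts=np.sort(starts),
        n_occurrences=n_occ,
        eids_used=eids,
        iteration=iteration,
        edits=tuple(sorted(mirrored)),
        genome_span=glen,
    )
    return seed, ext.expansions


def _consistent_positions(
    fwd: Seed, bwd: Seed, seg_start: int, tol: int
) -> np.ndarray:
    """Forward-seed starts whose backward partner lies at the expected
    genome distance (read-implied, within ±tol for indel drift)."""
    if len(fwd.genome_starts) == 0 or len(bwd.genome_starts) == 0:
        return np.empty(0, dtype=np.int64)
    expected = fwd.genome_starts + (bwd.read_start - seg_start)
    bstarts = bwd.genome_starts  # sorted
    idx = np.searchsorted(bstarts, expected - tol)
    ok = np.zeros(len(expected), dtype=bool)
    for i, (e, k) in enumerate(zip(expected, idx)):
        while k < len(bstarts) and bstarts[k] <= e + tol:
            ok[i] = True
            break
    return fwd.genome_starts[ok]


def bidirectional_align(
    index_fwd: FMIndex,
    index_rev: FMIndex,
    pattern: np.ndarray,
    budget: SearchBudget,
    start: int = 0,
    end: int | None = None,
    iteration: int = 1,
) -> SeedingResult:
    """One bidirectional pass over pattern[start:end).

    Fully aligned when either extension covers the whole segment, or
    when the two extensions meet/overlap and share a consistent genome
    placement. Otherwise the pass yields up to two seeds and the inner
    interval between their inner limits.
    """
    if end is None:
        end = len(pattern)
    if end - start < 1:
        raise ValueError("empty segment")
    expansions = 0

    bwd, exp = backward_extend(index_fwd, pattern, start, end, budget.backward, iteration)
    expansions += exp
    if bwd is not None and bwd.read_start == start:
        return SeedingResult(
            status="fully_aligned",
            full_hits=bwd.genome_starts,
            full_eids=bwd.eids_used,
            seeds=[bwd],
            expansions=expansions,
        )

    fwd, exp = forward_extend(index_rev, pattern, start, end, budget.forward, iteration)
    expansions += exp
    if fwd is not None and fwd.read_end == end:
        return SeedingResult(
            status="fully_aligned",
            full_hits=fwd.genome_starts,
            full_eids=fwd.eids_used,
            seeds=[fwd],
            expansions=expansions,
        )

    # meet condition: inner limits touch or overlap, plus a genome
    # placement consistent between the two extensions
    if fwd is not None and bwd is not None and fwd.read_end >= bwd.read_start:
        tol = budget.max_eids
        hits = _consistent_positions(fwd, bwd, start, tol)
        if len(hits) > 0:
            return SeedingResult(
                status="fully_aligned",
                full_hits=hits,
                full_eids=fwd.eids_used + bwd.eids_used,
                seeds=[fwd, bwd],
                expansions=expansions,
            )

    seeds = [s for s in (fwd, bwd) if s is not None]
    inner_start = fwd.read_end if fwd is not None else start
    inner_end = bwd.read_start if bwd is not None else end
    if inner_end < inner_start:  # overlapping but inconsistent extensions
        inner_start, inner_end = inner_end, inner_start
    return SeedingResult(
        status="seeded" if seeds else "unseeded",
        seeds=seeds,
        inner_limits=(inner_start, inner_end),
        expansions=expansions,
    )


def iterative_seed(
    index_fwd: FMIndex,
    index_rev: FMIndex,
    pattern: np.ndarray,
    budget: SearchBudget,
    min_inner_len: int = 15,
) -> SeedingResult:
    """Iteratively re-seed the shrinking unaligned inner segment.

    Each iteration runs one bidirectional pass on the current inner
    segment; its seeds' inner limits define the next segment, shrunk by
    one base at each end to step past the symbols where extension
    failed. The loop stops when the inner segment is shorter than
    ``min_inner_len``, when a pass yields no seed, or when a pass fully
    aligns its segment (iteration 1: the whole read is aligned; later
    iterations: the segment match becomes one more seed).
    """
    if min_inner_len < 1:
        raise ValueError("min_inner_len must be >= 1")
    start, end = 0, len(pattern)
    seeds: list[Seed] = []
    expansions = 0
    iteration = 1
    while True:
        res = bidirectional_align(
            index_fwd, index_rev, pattern, budget, start, end, iteration
        )
        expansions += res.expansions
        if res.status == "fully_aligned":
            if iteration == 1:
                return SeedingResult(
                    status="fully_aligned",
                    full_hits=res.full_hits,
                    full_eids=res.full_eids,
                    inner_limits=(start, end),
                    expansions=expansions,
                )
            # keep the contributing directional seed(s): they carry the
            # edit layout the assembly stage needs
            seeds.extend(res.seeds)
            break
        if not res.seeds:
            break
        seeds.extend(res.seeds)
        inner_start, inner_end = res.inner_limits
        # skip the failing symbol at each end: the next segment lies
        # strictly inside this iteration's inner limits
        start, end = inner_start + 1, inner_end - 1
        if end - start < min_inner_len:
            break
        iteration += 1
    return SeedingResult(
        status="seeded" if seeds else "unseeded",
        seeds=seeds,
        inner_limits=(start, end),
        expansions=expansions,
    )
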