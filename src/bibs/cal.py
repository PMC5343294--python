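"""Candidate Alignment Location (CAL) formation and ranking.

A CAL is a genome window in which the full read is subsequently
verified. One is formed by either rule A — a single seed whose read
coverage exceeds a threshold — or rule B — a maximal group of two or
more collinear seeds whose genome span (seed lengths included) stays
below the read length plus an edit-budget slack. Collinearity (read
order equals genome order, non-overlapping read intervals) is required
because a shuffled group cannot support one gapless-window alignment.

Maximal groups are exactly the maximal cliques of the pairwise
compatibility graph (both the span and the order constraints are
pairwise), found per connected component with Bron-Kerbosch; seed
placements are first sorted by genome position so the graph is local
and components stay small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from bibs.search import Seed

WINDOW_PAD = 8      # nt of window padding on each side, for indel drift
MAX_PLACEMENTS = 2000  # safety cap on (seed, position) pairs per read


@dataclass
class CAL:
    """A candidate genome window with the member seeds supporting it."""

    window_start: int  # global, 0-based half-open
    window_end: int
    strand: str
    members: list[tuple[Seed, int]]  # (seed, chosen genome start), read order
    chromosome: str | None = None
    covered_read: int = field(init=False)

    def __post_init__(self) -> None:
        self.covered_read = sum(s.read_end - s.read_start for s, _ in self.members)

    @property
    def n_seeds(self) -> int:
        return len(self.members)

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start


def _compatible(
    a: tuple[Seed, int], b: tuple[Seed, int], span_limit: int, overlap_tol: int = 0
) -> bool:
    """Rule-B pairwise test: disjoint read intervals, read order equal
    to genome order, joint genome span below the limit. A genome
    overlap up to ``overlap_tol`` is tolerated: EID branching can
    misplace an indel by a base or two at a seed edge."""
    (sa, pa), (sb, pb) = a, b
    if sa.read_start > sb.read_start:
        (sa, pa), (sb, pb) = (sb, pb), (sa, pa)
    if sa.read_end > sb.read_start:  # overlapping or identical read intervals
        return False
    if pa + sa.genome_span > pb + overlap_tol:  # genome order must match read order
        return False
    return (pb + sb.genome_span) - pa < span_limit


def _bron_kerbosch(adj: dict[int, set[int]], nodes: list[int]) -> list[set[int]]:
    cliques: list[set[int]] = []

    def expand(r: set[int], p: set[int], x: set[int]) -> None:
        if not p and not x:
            if len(r) >= 2:
                cliques.append(set(r))
            return
        pivot = max(p | x, key=lambda v: len(adj[v] & p))
        for v in list(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p.discard(v)
            x.add(v)

    expand(set(), set(nodes), set())
    return cliques


def _window(members: list[tuple[Seed, int]], read_len: int, budget_eids: int,
            bounds: tuple[int, int] | None) -> tuple[int, int]:
    """Extend the member span so the whole read fits, plus padding."""
    anchor = min(p - s.read_start for s, p in members)
    start = anchor - budget_eids - WINDOW_PAD
    end = anchor + read_len + budget_eids + WINDOW_PAD + read_len // 100
    if bounds is not None:
        start = max(start, bounds[0])
        end = min(end, bounds[1])
    return start, end


def build_cals(
    seeds: list[Seed],
    read_len: int,
    single_seed_min_len: int | None = None,
    budget_eids: int = 2,
    strand: str = "+",
    bounds_of=None,
) -> list[CAL]:
    """Form CALs from the seeds of one read on one strand.

    ``single_seed_min_len`` defaults to max(30, read_len/4).
    ``bounds_of`` optionally maps a global position to the enclosing
    chromosome's (start, end) global interval, used to clip windows.
    """
    if single_seed_min_len is None:
        single_seed_min_len = max(30, read_len // 4)
    # slack beyond the read length: edit-budget drift plus a ~1% indel
    # allowance so long multi-indel reads keep their true group
    span_limit = read_len + 2 * budget_eids + max(WINDOW_PAD, read_len // 100)

    placements: list[tuple[Seed, int]] = []
    for seed in sorted(seeds, key=lambda s: s.n_occurrences):
        for pos in seed.genome_starts:
            placements.append((seed, int(pos)))
            if len(placements) >= MAX_PLACEMENTS:
                break
        if len(placements) >= MAX_PLACEMENTS:
            break
    placements.sort(key=lambda sp: (sp[1], sp[0].read_start))

    cals: list[CAL] = []

    # rule B: maximal collinear groups of >= 2 seeds, via cliques of the
    # local compatibility graph
    n = len(placements)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if placements[j][1] - placements[i][1] >= span_limit:
                break
            if _compatible(placements[i], placements[j], span_limit, budget_eids):
                adj[i].add(j)
                adj[j].add(i)
    # connected components keep Bron-Kerbosch calls small
    seen: set[int] = set()
    for root in range(n):
        if root in seen or not adj[root]:
            seen.add(root)
            continue
        comp = []
        stack = [root]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(adj[v] - seen)
        for clique in _bron_kerbosch(adj, comp):
            members = sorted(
                (placements[i] for i in clique), key=lambda sp: sp[0].read_start
            )
            bounds = bounds_of(members[0][1]) if bounds_of else None
            ws, we = _window(members, read_len, budget_eids, bounds)
            cals.append(CAL(ws, we, strand, members))

    # rule A: one sufficiently long seed forms a CAL on its own
    # (low-specificity seeds are only admitted in groups)
    for seed in seeds:
        if seed.length > single_seed_min_len and not seed.low_specificity:
            for pos in seed.genome_starts:
                members = [(seed, int(pos))]
                bounds = bounds_of(int(pos)) if bounds_of else None
                ws, we = _window(members, read_len, budget_eids, bounds)
                cals.append(CAL(ws, we, strand, members))

    return _merge_duplicates(cals)


def _merge_duplicates(cals: list[CAL]) -> list[CAL]:
    """Merge CALs whose windows coincide within the padding."""
    if not cals:
        return []
    cals.sort(key=lambda c: (c.window_start, c.window_end))
    merged: list[CAL] = [cals[0]]
    for cal in cals[1:]:
        prev = merged[-1]
        if abs(cal.window_start - prev.window_start) <= WINDOW_PAD:
            keys = {(s.read_start, s.read_end, p) for s, p in prev.members}
            extra = [m for m in cal.members
                     if (m[0].read_start, m[0].read_end, m[1]) not in keys]
            if extra:
                members = sorted(prev.members + extra, key=lambda sp: sp[0].read_start)
                # keep only a collinear chain if the union broke order
                chain: list[tuple[Seed, int]] = []
                for m in members:
                    if not chain or (
                        chain[-1][0].read_end <= m[0].read_start
                        and chain[-1][1] + chain[-1][0].genome_span <= m[1]
                    ):
                        chain.append(m)
                merged[-1] = CAL(prev.window_start, prev.window_end, prev.strand,
                                 chain, prev.chromosome)
        else:
            merged.append(cal)
    return merged


def rank_cals(cals: list[CAL]) -> list[CAL]:
    """Order CALs by descending support.

    Key: number of member seeds, then total read coverage, then the
    smaller window; deterministic final tie-break by genome position.
    """
    return sorted(
        cals,
        key=lambda c: (-c.n_seeds, -c.covered_read, c.window_length, c.window_start),
    )
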