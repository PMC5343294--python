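"""Smith-Waterman gap filling and full-read alignment assembly.

Inside each CAL the member seeds already fix most of the read; only the
short unmapped segments between consecutive seeds (and any terminal
flanks) are aligned by dynamic programming, against the matching
sub-window of the converted genome text. The pieces are spliced into a
single CIGAR consuming the whole read; terminal bases that cannot be
anchored are soft-clipped.

Two affine-gap (Gotoh) kernels are provided: a local Smith-Waterman
with an optional band, and a fitting alignment (query global, reference
ends free) used for terminal flanks and for producing the CIGAR of
reads the BWT stage aligned in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from bibs.cal import CAL
from bibs.fmindex import encode

_NEG = -(10 ** 9)


@dataclass(frozen=True)
class ScoringScheme:
    """Integer alignment scores.

    Defaults penalize gaps clearly above substitutions: with a cheaper
    extend penalty, a multi-base terminal deletion reaching a chance
    2-3 nt match can outscore a pair of honest mismatches and drag the
    leftmost coordinate away from the true origin.
    """

    match: int = 5
    mismatch: int = -4
    gap_open: int = -10   # cost of the first base of a gap
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch score must be negative")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if abs(self.gap_open) < abs(self.gap_extend):
            raise ValueError("gap_open penalty must be >= gap_extend in magnitude")


@dataclass
class Alignment:
    """A final read placement (coordinates 0-based until SAM output)."""

    position: int        # global leftmost aligned position
    strand: str          # '+' (OT) or '-' (OB)
    cigar: str
    score: int
    edit_distance: int
    mapq: int = 0
    chromosome: str | None = None
    local_position: int | None = None
    matches: int = 0
    sw_cells: int = 0    # DP cells spent producing this alignment

    @property
    def bisulfite_strand_tag(self) -> str:
        return "OT" if self.strand == "+" else "OB"


@njit(cache=False)
def _sw_fill(ref, q, match, mismatch, go, ge, band):
    """Local affine-gap DP. band < 0 means full matrix.

    Returns H, E, F, pointer matrices and the best cell (first-found on
    ties, i.e. smallest ref index then smallest query index).
    """
    n, m = len(ref), len(q)
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in query (ref consumed)
    F = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in ref (query consumed)
    PH = np.zeros((n + 1, m + 1), np.uint8)      # 0 stop, 1 diag, 2 up, 3 left
    PE = np.zeros((n + 1, m + 1), np.uint8)      # 1 = opened from H
    PF = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        jlo, jhi = 1, m
        if band >= 0:
            jlo = max(1, i - band)
            jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            e_open = H[i - 1, j] + go
            e_ext = E[i - 1, j] + ge
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i, j - 1] + go
            f_ext = F[i, j - 1] + ge
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 1
            else:
                F[i, j] = f_ext
            a = ref[i - 1]
            b = q[j - 1]
            s = match if (a == b and a != 5) else mismatch
            h = H[i - 1, j - 1] + s
            ph = 1
            if E[i, j] > h:
                h = E[i, j]
                ph = 2
            if F[i, j] > h:
                h = F[i, j]
                ph = 3
            if h <= 0:
                h = 0
                ph = 0
            H[i, j] = h
            PH[i, j] = ph
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, PH, PE, PF, best, bi, bj


@njit(cache=False)
def _fit_fill(ref, q, match, mismatch, go, ge, anchor_ref_start, band):
    """Fitting alignment: query aligned end to end, reference ends free
    (the start anchored when requested). Affine gaps; band < 0 computes
    the full matrix, otherwise cells with |i - j| > band are skipped
    (the band must cover the ref/query length difference)."""
    n, m = len(ref), len(q)
    H = np.full((n + 1, m + 1), _NEG, np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    PH = np.zeros((n + 1, m + 1), np.uint8)
    PE = np.zeros((n + 1, m + 1), np.uint8)
    PF = np.zeros((n + 1, m + 1), np.uint8)
    H[0, 0] = 0
    for i in range(1, n + 1):
        if not anchor_ref_start:
            H[i, 0] = 0
    for j in range(1, m + 1):
        H[0, j] = go + (j - 1) * ge
        PH[0, j] = 3
        F[0, j] = H[0, j]
    for i in range(1, n + 1):
        jlo, jhi = 1, m
        if band >= 0:
            jlo = max(1, i - band)
            jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            e_open = H[i - 1, j] + go
            e_ext = E[i - 1, j] + ge
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i, j - 1] + go
            f_ext = F[i, j - 1] + ge
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 1
            else:
                F[i, j] = f_ext
            a = ref[i - 1]
            b = q[j - 1]
            s = match if (a == b and a != 5) else mismatch
            h = H[i - 1, j - 1] + s
            ph = 1
            if E[i, j] > h:
                h = E[i, j]
                ph = 2
            if F[i, j] > h:
                h = F[i, j]
                ph = 3
            H[i, j] = h
            PH[i, j] = ph
    return H, E, F, PH, PE, PF


@njit(cache=False)
def _sw_fill_banded(ref, q, match, mismatch, go, ge, band):
    """Local affine-gap DP with banded storage: column c = j - i + band.

    Memory is O(n x band) instead of O(n x m); paths are confined to
    |i - j| <= band. Out-of-band cells read as empty (score 0 with no
    pointer), which cannot create an in-band path that the full matrix
    lacks."""
    n, m = len(ref), len(q)
    W = 2 * band + 1
    H = np.zeros((n + 1, W), np.int32)
    E = np.full((n + 1, W), _NEG, np.int32)
    F = np.full((n + 1, W), _NEG, np.int32)
    PH = np.zeros((n + 1, W), np.uint8)
    PE = np.zeros((n + 1, W), np.uint8)
    PF = np.zeros((n + 1, W), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        jlo = max(1, i - band)
        jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            c = j - i + band
            h_up = H[i - 1, c + 1] if c + 1 < W else _NEG
            e_up = E[i - 1, c + 1] if c + 1 < W else _NEG
            e_open = h_up + go
            e_ext = e_up + ge
            if e_open >= e_ext:
                E[i, c] = e_open
                PE[i, c] = 1
            else:
                E[i, c] = e_ext
            h_left = H[i, c - 1] if c - 1 >= 0 else _NEG
            f_left = F[i, c - 1] if c - 1 >= 0 else _NEG
            f_open = h_left + go
            f_ext = f_left + ge
            if f_open >= f_ext:
                F[i, c] = f_open
                PF[i, c] = 1
            else:
                F[i, c] = f_ext
            a = ref[i - 1]
            b = q[j - 1]
            s = match if (a == b and a != 5) else mismatch
            h = H[i - 1, c] + s  # diagonal keeps the same banded column
            ph = 1
            if E[i, c] > h:
                h = E[i, c]
                ph = 2
            if F[i, c] > h:
                h = F[i, c]
                ph = 3
            if h <= 0:
                h = 0
                ph = 0
            H[i, c] = h
            PH[i, c] = ph
            if h > best:
                best = h
                bi = i
                bj = j
    return PH, PE, PF, best, bi, bj


@njit(cache=False)
def _fit_fill_banded(ref, q, match, mismatch, go, ge, anchor_ref_start, band):
    """Banded-storage fitting alignment (see _fit_fill); the band must
    cover the ref/query length difference."""
    n, m = len(ref), len(q)
    W = 2 * band + 1
    H = np.full((n + 1, W), _NEG, np.int32)
    E = np.full((n + 1, W), _NEG, np.int32)
    F = np.full((n + 1, W), _NEG, np.int32)
    PH = np.zeros((n + 1, W), np.uint8)
    PE = np.zeros((n + 1, W), np.uint8)
    PF = np.zeros((n + 1, W), np.uint8)
    H[0, band] = 0
    for i in range(1, min(n, band) + 1):
        if not anchor_ref_start:
            H[i, band - i] = 0
    for j in range(1, min(m, band) + 1):
        H[0, j + band] = go + (j - 1) * ge
        PH[0, j + band] = 3
        F[0, j + band] = H[0, j + band]
    for i in range(1, n + 1):
        jlo = max(1, i - band)
        jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            c = j - i + band
            h_up = H[i - 1, c + 1] if c + 1 < W else _NEG
            e_up = E[i - 1, c + 1] if c + 1 < W else _NEG
            e_open = h_up + go
            e_ext = e_up + ge
            if e_open >= e_ext:
                E[i, c] = e_open
                PE[i, c] = 1
            else:
                E[i, c] = e_ext
            h_left = H[i, c - 1] if c - 1 >= 0 else _NEG
            f_left = F[i, c - 1] if c - 1 >= 0 else _NEG
            f_open = h_left + go
            f_ext = f_left + ge
            if f_open >= f_ext:
                F[i, c] = f_open
                PF[i, c] = 1
            else:
                F[i, c] = f_ext
            a = ref[i - 1]
            b = q[j - 1]
            s = match if (a == b and a != 5) else mismatch
            h = H[i - 1, c] + s
            ph = 1
            if E[i, c] > h:
                h = E[i, c]
                ph = 2
            if F[i, c] > h:
                h = F[i, c]
                ph = 3
            H[i, c] = h
            PH[i, c] = ph
    return H, PH, PE, PF


class _BandView:
    """Adapter exposing banded-storage pointer matrices as [i, j]."""

    __slots__ = ("mat", "band")

    def __init__(self, mat, band):
        self.mat = mat
        self.band = band

    def __getitem__(self, key):
        i, j = key
        c = j - i + self.band
        if c < 0 or c >= self.mat.shape[1]:
            return 0
        return self.mat[i, c]


def _traceback(PH, PE, PF, i, j, local: bool):
    """Walk pointers back from (i, j); returns (ops, ref_start, q_start).

    ops are (op, length) pairs in read order, op in {M, D, I}.
    """
    ops: list[tuple[str, int]] = []

    def push(op):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    state = 0  # 0 = H, 1 = E, 2 = F
    while j > 0:
        if state == 0:
            ph = PH[i, j]
            if ph == 0:
                break
            if ph == 1:
                push("M")
                i -= 1
                j -= 1
            elif ph == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            push("D")
            opened = PE[i, j]
            i -= 1
            if opened:
                state = 0
        else:
            push("I")
            opened = PF[i, j]
            j -= 1
            if opened:
                state = 0
        if i == 0 and j == 0:
            break
    ops.reverse()
    return ops, i, j


def smith_waterman(
    ref_seg: str | np.ndarray,
    read_seg: str | np.ndarray,
    scheme: ScoringScheme = ScoringScheme(),
    band: int = -1,
):
    """Optimal local alignment of two segments.

    Returns (score, path) where path is (ref_start, ref_end, read_start,
    read_end, ops); the empty read segment scores 0 with an empty path.
    Ties in the best cell resolve to the smallest reference then read
    index; path ties prefer diagonal over up over left.
    """
    ref = encode(ref_seg) if isinstance(ref_seg, str) else ref_seg
    q = encode(read_seg) if isinstance(read_seg, str) else read_seg
    if len(q) == 0 or len(ref) == 0:
        return 0, (0, 0, 0, 0, [])
    if band >= 0 and 2 * band + 1 < len(q):
        PH, PE, PF, best, bi, bj = _sw_fill_banded(
            ref, q, scheme.match, scheme.mismatch,
            scheme.gap_open, scheme.gap_extend, band,
        )
        PH = _BandView(PH, band)
        PE = _BandView(PE, band)
        PF = _BandView(PF, band)
    else:
        _, _, _, PH, PE, PF, best, bi, bj = _sw_fill(
            ref, q, scheme.match, scheme.mismatch,
            scheme.gap_open, scheme.gap_extend, band,
        )
    if best <= 0:
        return 0, (0, 0, 0, 0, [])
    ops, ri, qj = _traceback(PH, PE, PF, bi, bj, local=True)
    return int(best), (int(ri), int(bi), int(qj), int(bj), ops)


def fitting_align(
    ref_seg: np.ndarray,
    read_seg: np.ndarray,
    scheme: ScoringScheme,
    anchor_ref_start: bool = False,
    anchor_ref_end: bool = False,
    band: int | None = None,
):
    """Align the whole read segment inside the reference segment.

    Returns (score, ref_start, ref_end, ops). Reference bases outside
    [ref_start, ref_end) are unused window; the read is fully consumed.
    The default band covers the length difference plus a small indel
    allowance; pass band=-1 for the full matrix.
    """
    n, m = len(ref_seg), len(read_seg)
    if m == 0:
        return 0, 0, 0, []
    if band is None:
        band = abs(n - m) + 8
    if band >= 0 and 2 * band + 1 < m:
        H, PH, PE, PF = _fit_fill_banded(
            ref_seg, read_seg, scheme.match, scheme.mismatch,
            scheme.gap_open, scheme.gap_extend, anchor_ref_start, band,
        )
        Hv = _BandView(H, band)
        PH = _BandView(PH, band)
        PE = _BandView(PE, band)
        PF = _BandView(PF, band)
        if anchor_ref_end:
            bi = n
        else:
            bi = max(
                range(max(0, m - band), min(n, m + band) + 1),
                key=lambda i: Hv[i, m],
            )
        score = int(Hv[bi, m])
    else:
        H, E, F, PH, PE, PF = _fit_fill(
            ref_seg, read_seg, scheme.match, scheme.mismatch,
            scheme.gap_open, scheme.gap_extend, anchor_ref_start, band,
        )
        if anchor_ref_end:
            bi = n
        else:
            bi = int(np.argmax(H[:, m]))
        score = int(H[bi, m])
    ops, ri, qj = _traceback(PH, PE, PF, bi, m, local=False)
    return score, int(ri), int(bi), ops


def _ops_to_cigar(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{ln}{op}" for op, ln in ops)


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, ln in ops:
        if ln == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def _score_ops(
    pattern: np.ndarray, text: np.ndarray, pos: int, ops: list[tuple[str, int]],
    scheme: ScoringScheme,
) -> tuple[int, int, int]:
    """Recompute (score, edit_distance, matches) of an assembled path
    in converted space, walking the CIGAR against the genome text."""
    score = 0
    nm = 0
    matches = 0
    i = pos
    j = 0
    for op, ln in ops:
        if op == "S":
            j += ln
        elif op == "M":
            for k in range(ln):
                a = text[i + k]
                b = pattern[j + k]
                if a == b and a != 5:
                    score += scheme.match
                    matches += 1
                else:
                    score += scheme.mismatch
                    nm += 1
            i += ln
            j += ln
        elif op == "D":
            score += scheme.gap_open + (ln - 1) * scheme.gap_extend
            nm += ln
            i += ln
        elif op == "I":
            score += scheme.gap_open + (ln - 1) * scheme.gap_extend
            nm += ln
            j += ln
    return score, nm, matches


def _seed_block(seed, pos: int) -> tuple[list[tuple[str, int]], int]:
    """Expand a seed's recorded edits into (ops, genome_end)."""
    ops: list[tuple[str, int]] = []
    rpos = seed.read_start
    for off, op, _base in seed.edits:
        if op == "X":
            ops.append(("M", off + 1 - rpos))
            rpos = off + 1
        elif op == "I":
            ops.append(("M", off - rpos))
            ops.append(("I", 1))
            rpos = off + 1
        elif op == "D":
            ops.append(("M", off - rpos))
            ops.append(("D", 1))
            rpos = off
    ops.append(("M", seed.read_end - rpos))
    return _merge_ops(ops), pos + seed.genome_span


class InconsistentSeedGeometry(ValueError):
    """Member seeds of a CAL contradict each other's placement."""


def fill_and_assemble(
    cal: CAL,
    pattern: np.ndarray,
    text: np.ndarray,
    scheme: ScoringScheme = ScoringScheme(),
    min_identity: float = 0.80,
    min_gap_score: float = 0.60,
    gap_score_min_len: int = 16,
) -> Alignment | None:
    """Verify one CAL: SW-fill inter-seed gaps, splice the full CIGAR.

    Returns None when a long gap scores below ``min_gap_score`` of its
    maximum, or the assembled identity (matches / read length) falls
    below ``min_identity``. Seed blocks are imported directly from the
    search stage's recorded edits.
    """
    read_len = len(pattern)
    members = cal.members
    if not members:
        return None
    # geometry check; small genome overlaps (EID drift at seed edges)
    # are handled by the whole-window fallback below
    needs_fallback = False
    for (s1, p1), (s2, p2) in zip(members, members[1:]):
        if s1.read_end > s2.read_start or p1 + s1.genome_span > p2 + 4:
            raise InconsistentSeedGeometry(
                f"seeds at read {s1.read_start}-{s1.read_end}/{s2.read_start}-"
                f"{s2.read_end} map to genome {p1}/{p2} out of order"
            )
        if p1 + s1.genome_span > p2:
            needs_fallback = True
    if needs_fallback:
        return _window_fallback(cal, pattern, text, scheme, min_identity)

    sw_cells = 0
    ops: list[tuple[str, int]] = []
    first_seed, first_pos = members[0]
    position = first_pos

    # left flank: anchored at the first seed's genome start
    flank = first_seed.read_start
    if flank > 0:
        ref_lo = max(cal.window_start, first_pos - flank - WINDOW_SLACK)
        ref_seg = text[ref_lo:first_pos][::-1].copy()
        read_seg = pattern[:flank][::-1].copy()
        if len(ref_seg) == 0:
            ops.append(("S", flank))
        else:
            score, _, ref_end, fops = fitting_align(
                ref_seg, read_seg, scheme, anchor_ref_start=True
            )
            sw_cells += (len(ref_seg) + 1) * (flank + 1)
            fops = [(op, ln) for op, ln in reversed(fops)]
            glen = sum(ln for op, ln in fops if op in ("M", "D"))
            _, _, fmatches = _score_ops(pattern, text, first_pos - glen, fops, scheme)
            if flank >= 8 and fmatches < 0.5 * flank:
                ops.append(("S", flank))
            else:
                ops.extend(fops)
                position = first_pos - glen

    cur_seed_ops, gend = _seed_block(first_seed, first_pos)
    ops.extend(cur_seed_ops)

    # inter-seed gaps
    prev_read_end = first_seed.read_end
    prev_gend = gend
    for seed, pos in members[1:]:
        rl = seed.read_start - prev_read_end
        gl = pos - prev_gend
        if rl == 0 and gl == 0:
            pass
        elif rl == 0:
            ops.append(("D", gl))
        elif gl == 0:
            ops.append(("I", rl))
        else:
            gap_ops, gap_cells, gap_score = _fill_gap(
                text[prev_gend:pos], pattern[prev_read_end:seed.read_start], scheme
            )
            sw_cells += gap_cells
            if rl >= gap_score_min_len and gap_score < min_gap_score * scheme.match * rl:
                return None
            ops.extend(gap_ops)
        block_ops, prev_gend = _seed_block(seed, pos)
        ops.extend(block_ops)
        prev_read_end = seed.read_end

    # right flank: anchored at the last seed's genome end
    flank = read_len - prev_read_end
    if flank > 0:
        ref_hi = min(cal.window_end, prev_gend + flank + WINDOW_SLACK)
        ref_seg = text[prev_gend:ref_hi]
        read_seg = pattern[prev_read_end:]
        if len(ref_seg) == 0:
            ops.append(("S", flank))
        else:
            score, _, ref_end, fops = fitting_align(
                ref_seg, read_seg, scheme, anchor_ref_start=True
            )
            sw_cells += (len(ref_seg) + 1) * (flank + 1)
            glen = sum(ln for op, ln in fops if op in ("M", "D"))
            _, _, fmatches = _score_ops(
                pattern[prev_read_end:], text, prev_gend, fops, scheme
            )
            if flank >= 8 and fmatches < 0.5 * flank:
                ops.append(("S", flank))
            else:
                ops.extend(fops)

    ops = _merge_ops(ops)
    # trim leading/trailing pure-indel artifacts into soft clips
    ops, position = _normalize_ends(ops, position)
    consumed = sum(ln for op, ln in ops if op in ("M", "I", "S"))
    if consumed != read_len:
        raise AssertionError(
            f"CIGAR consumes {consumed} of {read_len} read bases: {ops}"
        )
    score, nm, matches = _score_ops(pattern, text, position, ops, scheme)
    if matches < min_identity * read_len:
        return None
    return Alignment(
        position=position,
        strand=cal.strand,
        cigar=_ops_to_cigar(ops),
        score=score,
        edit_distance=nm,
        matches=matches,
        sw_cells=sw_cells,
    )


WINDOW_SLACK = 8  # extra reference bases allowed around flanks


def _window_fallback(
    cal: CAL, pattern: np.ndarray, text: np.ndarray, scheme: ScoringScheme,
    min_identity: float,
) -> Alignment | None:
    """Align the whole read against the CAL window in one fitting pass.

    Used when seed geometry is self-consistent only up to a small
    overlap; costs window x read cells but is rare."""
    aln = align_read_in_window(
        pattern, text, cal.window_start, cal.window_end, cal.strand, scheme
    )
    band = abs(cal.window_length - len(pattern)) + 8
    aln.sw_cells = (len(pattern) + 1) * (2 * band + 1)
    if aln.matches < min_identity * len(pattern):
        return None
    return aln


def _fill_gap(ref_seg: np.ndarray, read_seg: np.ndarray, scheme: ScoringScheme):
    """Align one inter-seed gap; splice the local SW path into a path
    consuming the whole gap (unaligned remainders become matches padded
    with indels at the outer edges)."""
    rl = len(read_seg)
    gl = len(ref_seg)
    # the band need only cover the ref/read length difference plus
    # drift: a genuine inter-seed gap is near-diagonal
    band = abs(gl - rl) + 2 * WINDOW_SLACK + 16
    score, (r0, r1, q0, q1, sw_ops) = smith_waterman(ref_seg, read_seg, scheme, band)
    cells = (gl + 1) * (rl + 1) if band < 0 else min((gl + 1) * (rl + 1),
                                                     (gl + 1) * (2 * band + 1))
    ops: list[tuple[str, int]] = []

    def pad(ref_n: int, read_n: int):
        common = min(ref_n, read_n)
        if ref_n > read_n:
            ops.append(("D", ref_n - read_n))
        elif read_n > ref_n:
            ops.append(("I", read_n - ref_n))
        if common:
            ops.append(("M", common))

    pad(r0, q0)
    ops.extend(sw_ops)
    ref_rest = gl - r1
    read_rest = rl - q1
    common = min(ref_rest, read_rest)
    if common:
        ops.append(("M", common))
    if ref_rest > read_rest:
        ops.append(("D", ref_rest - read_rest))
    elif read_rest > ref_rest:
        ops.append(("I", read_rest - ref_rest))
    return _merge_ops(ops), cells, score


def _normalize_ends(ops: list[tuple[str, int]], position: int):
    """Convert terminal I/D runs to soft clips / position shifts."""
    while ops:
        op, ln = ops[0]
        if op == "D":
            position += ln
            ops = ops[1:]
        elif op == "I":
            ops = [("S", ln)] + ops[1:]
            break
        else:
            break
    while ops:
        op, ln = ops[-1]
        if op == "D":
            ops = ops[:-1]
        elif op == "I":
            ops = ops[:-1] + [("S", ln)]
            break
        else:
            break
    # merge S runs created adjacent to existing S
    return _merge_ops(ops), position


def align_read_in_window(
    pattern: np.ndarray,
    text: np.ndarray,
    window_start: int,
    window_end: int,
    strand: str,
    scheme: ScoringScheme = ScoringScheme(),
) -> Alignment:
    """Fitting alignment of a whole read inside a genome window.

    Used to produce the CIGAR of reads the BWT stage fully aligned
    (possibly with a few EIDs whose exact layout the interval search
    does not retain).
    """
    ref_seg = text[window_start:window_end]
    score, r0, r1, ops = fitting_align(ref_seg, pattern, scheme)
    ops, position = _normalize_ends(_merge_ops(ops), window_start + r0)
    score, nm, matches = _score_ops(pattern, text, position, ops, scheme)
    return Alignment(
        position=position,
        strand=strand,
        cigar=_ops_to_cigar(ops),
        score=score,
        edit_distance=nm,
        matches=matches,
        sw_cells=0,
    )


def pick_best(alignments: list[Alignment]) -> tuple[Alignment, int]:
    """Select the primary alignment and its mapping quality.

    Primary: maximum score, ties by smaller edit distance then smaller
    genome coordinate. MAPQ: 60 for a lone candidate, otherwise
    min(60, 0.4 x (best - second-best score)), and 0 on an exact
    score-and-distance tie.
    """
    if not alignments:
        raise ValueError("pick_best requires at least one alignment")
    ordered = sorted(
        alignments, key=lambda a: (-a.score, a.edit_distance, a.position)
    )
    best = ordered[0]
    if len(ordered) == 1:
        best.mapq = 60
        return best, 60
    second = ordered[1]
    if best.score == second.score and best.edit_distance == second.edit_distance:
        mapq = 0
    else:
        mapq = min(60, round(0.4 * (best.score - second.score)))
    best.mapq = mapq
    return best, mapq
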