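"""FM-index over a nucleotide text: BWT, rank checkpoints, sampled SA.

Alphabet encoding: ``$``=0 (sentinel, lexicographically smallest),
A=1, C=2, G=3, T=4, N=5. N is indexed as a literal fifth symbol but the
search layer never lets a read base match it, so assembly gaps cannot
produce spurious seeds.

The suffix array is built by numpy prefix doubling (O(n log n) sorts);
rank queries combine stride-``occ_stride`` checkpoints with a short
in-block scan, and locate walks the LF mapping to the nearest sampled
suffix-array row. The hot loops are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

SENTINEL = 0
ALPHABET = "$ACGTN"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate(ALPHABET):
    _CODE[ord(_ch)] = _i
N_CODE = 5

_MAGIC = "BIBS-FMI-1"


def encode(text: str) -> np.ndarray:
    """Encode an ACGTN string to uint8 codes (no sentinel appended)."""
    arr = _CODE[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]
    if (arr <= 0).any():
        bad = text[int(np.argmax(arr <= 0))]
        raise ValueError(f"symbol {bad!r} outside ACGTN alphabet")
    return arr.astype(np.uint8)


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def _suffix_array(t: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling."""
    n = t.size
    rank = t.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    if n == 1:
        return sa
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        diff = np.empty(n, dtype=np.int64)
        diff[0] = 0
        diff[1:] = (rank[sa[1:]] != rank[sa[:-1]]) | (key2[sa[1:]] != key2[sa[:-1]])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.cumsum(diff)
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


@njit(cache=False)
def _rank(bwt, checkpoints, stride, c, i):
    """Occurrences of symbol c in bwt[0:i]."""
    block = i // stride
    r = checkpoints[block, c]
    for j in range(block * stride, i):
        if bwt[j] == c:
            r += 1
    return r


@njit(cache=False)
def _step(bwt, checkpoints, stride, c_array, c, lo, hi):
    """One backward-search step: prepend symbol c to the current match."""
    lo2 = c_array[c] + _rank(bwt, checkpoints, stride, c, lo)
    hi2 = c_array[c] + _rank(bwt, checkpoints, stride, c, hi)
    return lo2, hi2


@njit(cache=False)
def _extend_exact(bwt, checkpoints, stride, c_array, pattern, j, lo, hi):
    """Extend backwards through pattern[..j], one symbol at a time.

    Returns (fail_index, lo, hi, steps): the interval before the first
    symbol that emptied it (fail_index == -1 when the whole prefix
    matched). A pattern N (code 5) never matches and fails immediately.
    ``steps`` counts FM-interval expansions (search-tree size metric).
    """
    steps = 0
    while j >= 0:
        c = pattern[j]
        if c == N_CODE:
            return j, lo, hi, steps
        lo2, hi2 = _step(bwt, checkpoints, stride, c_array, c, lo, hi)
        steps += 1
        if lo2 >= hi2:
            return j, lo, hi, steps
        lo, hi = lo2, hi2
        j -= 1
    return -1, lo, hi, steps


@njit(cache=False)
def _extend_exact_trace(bwt, checkpoints, stride, c_array, pattern, j, lo, hi,
                        lo_hist, hi_hist):
    """Like _extend_exact but records the interval after each matched
    symbol: hist[t] is the interval after matching pattern[j - t]."""
    steps = 0
    t = 0
    while j >= 0:
        c = pattern[j]
        if c == N_CODE:
            return j, lo, hi, steps
        lo2, hi2 = _step(bwt, checkpoints, stride, c_array, c, lo, hi)
        steps += 1
        if lo2 >= hi2:
            return j, lo, hi, steps
        lo, hi = lo2, hi2
        lo_hist[t] = lo
        hi_hist[t] = hi
        t += 1
        j -= 1
    return -1, lo, hi, steps


@njit(cache=False)
def _locate_row(bwt, checkpoints, stride, c_array, sa_lookup, row):
    """Text position of the suffix at BWT row, via LF walk to a sample."""
    steps = 0
    while sa_lookup[row] < 0:
        c = bwt[row]
        row = c_array[c] + _rank(bwt, checkpoints, stride, c, row)
        steps += 1
    return sa_lookup[row] + steps


@njit(cache=False)
def _locate_range(bwt, checkpoints, stride, c_array, sa_lookup, lo, hi, out):
    for i in range(hi - lo):
        out[i] = _locate_row(bwt, checkpoints, stride, c_array, sa_lookup, lo + i)
    return out


@dataclass
class FMIndex:
    """BWT + C array + occ checkpoints + sampled suffix array."""

    bwt: np.ndarray          # uint8, length text_length + 1
    c_array: np.ndarray      # int64, length 7 (cumulative, c_array[c]..c_array[c+1])
    checkpoints: np.ndarray  # int32, (nblocks, 6) occ counts before each block
    occ_stride: int
    sa_lookup: np.ndarray    # int32, -1 where unsampled
    sa_stride: int
    text_length: int         # excludes the sentinel

    @property
    def size(self) -> int:
        """Number of BWT rows (text_length + 1)."""
        return self.text_length + 1

    def rank(self, c: int, i: int) -> int:
        return int(_rank(self.bwt, self.checkpoints, self.occ_stride, c, i))

    def extend_exact(self, pattern: np.ndarray, j: int, lo: int, hi: int):
        """Backward-extend pattern[..j] starting from interval [lo, hi)."""
        fail, lo2, hi2, steps = _extend_exact(
            self.bwt, self.checkpoints, self.occ_stride, self.c_array,
            pattern, j, lo, hi,
        )
        return int(fail), int(lo2), int(hi2), int(steps)

    def extend_exact_trace(self, pattern: np.ndarray, j: int, lo: int, hi: int,
                           lo_hist: np.ndarray, hi_hist: np.ndarray):
        """extend_exact recording per-step intervals into the hist arrays."""
        fail, lo2, hi2, steps = _extend_exact_trace(
            self.bwt, self.checkpoints, self.occ_stride, self.c_array,
            pattern, j, lo, hi, lo_hist, hi_hist,
        )
        return int(fail), int(lo2), int(hi2), int(steps)

    def step(self, c: int, lo: int, hi: int) -> tuple[int, int]:
        lo2, hi2 = _step(
            self.bwt, self.checkpoints, self.occ_stride, self.c_array, c, lo, hi
        )
        return int(lo2), int(hi2)

    def backward_search(self, pattern: str | np.ndarray) -> tuple[int, int]:
        """Suffix-array interval [lo, hi) of all occurrences of pattern."""
        codes = encode(pattern) if isinstance(pattern, str) else pattern
        lo, hi = 0, self.size
        fail, lo, hi, _ = _extend_exact(
            self.bwt, self.checkpoints, self.occ_stride, self.c_array,
            codes, len(codes) - 1, lo, hi,
        )
        if fail != -1:
            return 0, 0
        return int(lo), int(hi)

    def locate(self, lo: int, hi: int, cap: int | None = None) -> np.ndarray:
        """Text positions for SA rows [lo, hi), optionally capped."""
        n = hi - lo
        if cap is not None:
            n = min(n, cap)
        out = np.empty(n, dtype=np.int64)
        _locate_range(
            self.bwt, self.checkpoints, self.occ_stride, self.c_array,
            self.sa_lookup, lo, lo + n, out,
        )
        return out

    def count(self, pattern: str | np.ndarray) -> int:
        lo, hi = self.backward_search(pattern)
        return hi - lo

    def reconstruct_text(self) -> str:
        """Invert the BWT (round-trip check; O(n) LF walks)."""
        n = self.size
        out = np.empty(n - 1, dtype=np.uint8)
        row = 0  # row of the sentinel-terminated rotation; bwt[0] is last char
        for i in range(n - 1):
            c = self.bwt[row]
            out[n - 2 - i] = c
            row = int(self.c_array[c]) + self.rank(int(c), row)
        return decode(out)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            magic=np.frombuffer(_MAGIC.encode(), dtype=np.uint8),
            bwt=self.bwt,
            c_array=self.c_array,
            checkpoints=self.checkpoints,
            occ_stride=np.int64(self.occ_stride),
            sa_lookup=self.sa_lookup,
            sa_stride=np.int64(self.sa_stride),
            text_length=np.int64(self.text_length),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FMIndex":
        data = np.load(path)
        magic = bytes(data["magic"]).decode()
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a bibs FM-index (magic {magic!r})")
        return cls(
            bwt=data["bwt"],
            c_array=data["c_array"],
            checkpoints=data["checkpoints"],
            occ_stride=int(data["occ_stride"]),
            sa_lookup=data["sa_lookup"],
            sa_stride=int(data["sa_stride"]),
            text_length=int(data["text_length"]),
        )


def build_fm_index(
    text: str | np.ndarray, occ_stride: int = 64, sa_stride: int = 8
) -> FMIndex:
    """Build the FM-index of ``text`` (sentinel appended internally)."""
    codes = encode(text) if isinstance(text, str) else text
    if codes.size == 0:
        raise ValueError("cannot index an empty text")
    n = codes.size
    t = np.empty(n + 1, dtype=np.uint8)
    t[:n] = codes
    t[n] = SENTINEL
    sa = _suffix_array(t)
    bwt = t[(sa - 1) % (n + 1)]

    counts = np.bincount(bwt, minlength=6).astype(np.int64)
    c_array = np.zeros(7, dtype=np.int64)
    c_array[1:] = np.cumsum(counts)

    nblocks = (n + 1) // occ_stride + 1
    checkpoints = np.zeros((nblocks, 6), dtype=np.int32)
    for c in range(6):
        cum = np.cumsum(bwt == c)
        ends = np.arange(1, nblocks) * occ_stride
        checkpoints[1:, c] = cum[ends - 1]

    sa_lookup = np.full(n + 1, -1, dtype=np.int32)
    sampled = (sa % sa_stride) == 0
    sa_lookup[sampled] = sa[sampled]

    return FMIndex(
        bwt=bwt,
        c_array=c_array,
        checkpoints=checkpoints,
        occ_stride=occ_stride,
        sa_lookup=sa_lookup,
        sa_stride=sa_stride,
        text_length=n,
    )
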