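"""Per-cytosine methylation calling from final alignments.

Bisulfite leaves methylated cytosines intact and converts unmethylated
ones to uracil (sequenced T). On the original-top (OT) strand a read C
over a genomic C therefore means methylated and a read T unmethylated;
on the original-bottom (OB) strand the readout is mirrored to G/A over
genomic Gs, because the aligned (reference-orientation) sequence of an
OB read is the reverse complement of what was sequenced.

Context (CpG / CHG / CHH) always comes from the unconverted genome,
strand-aware: for a bottom-strand cytosine (top-strand G) the two
following bases run leftwards on the complement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from bibs.genome import ReferenceGenome

_CIGAR_RE = re.compile(r"(\d+)([MIDSH=X])")

#: per-read methylation string characters, Bismark XM-style
_XM_CHAR = {
    ("CpG", "methylated"): "Z",
    ("CpG", "unmethylated"): "z",
    ("CHG", "methylated"): "X",
    ("CHG", "unmethylated"): "x",
    ("CHH", "methylated"): "H",
    ("CHH", "unmethylated"): "h",
}


@dataclass(frozen=True)
class MethylationCall:
    chromosome: str
    genome_position: int  # 0-based position of the cytosine (its own strand)
    strand: str           # '+' top-strand C, '-' bottom-strand C (top G)
    context: str          # CpG | CHG | CHH
    status: str           # methylated | unmethylated | ambiguous
    read_id: str


def cytosine_context(genome: ReferenceGenome, chrom: str, pos: int, strand: str) -> str | None:
    """Context of the cytosine at (chrom, pos) on the given strand.

    Returns None when the two downstream bases run off the chromosome
    or contain N (context undeterminable).
    """
    seq = genome.sequences[chrom]
    if strand == "+":
        if pos + 2 >= len(seq):
            return None
        n1, n2 = seq[pos + 1], seq[pos + 2]
        if n1 == "G":
            return "CpG"
        if n1 == "N" or n2 == "N":
            return None
        return "CHG" if n2 == "G" else "CHH"
    else:
        if pos - 2 < 0:
            return None
        n1, n2 = seq[pos - 1], seq[pos - 2]  # complement: C here means G pairs
        if n1 == "C":
            return "CpG"
        if n1 == "N" or n2 == "N":
            return None
        return "CHG" if n2 == "C" else "CHH"


def _aligned_pairs(cigar: str, pos: int):
    """Yield (ref_pos, read_index | None) for reference-consuming ops."""
    i = pos
    j = 0
    for ln, op in _CIGAR_RE.findall(cigar):
        ln = int(ln)
        if op in ("M", "=", "X"):
            for k in range(ln):
                yield i + k, j + k
            i += ln
            j += ln
        elif op == "D":
            for k in range(ln):
                yield i + k, None
            i += ln
        elif op in ("I", "S"):
            j += ln


def call_methylation(aln, seq: str, genome: ReferenceGenome) -> list[MethylationCall]:
    """Methylation calls for one alignment.

    ``seq`` is the aligned read sequence in reference orientation (the
    SAM SEQ field: for OB-strand alignments, the reverse complement of
    the sequenced read). Cytosines under soft clips are uncovered and
    skipped; a deletion over a cytosine is ambiguous, as is any read
    base that bisulfite chemistry cannot produce there.
    """
    chrom = aln.chromosome
    pos = aln.local_position
    cseq = genome.sequences[chrom]
    bs_strand = aln.strand  # '+': genomic Cs read as C/T; '-': Gs as G/A
    calls: list[MethylationCall] = []
    for ref_pos, read_idx in _aligned_pairs(aln.cigar, pos):
        gbase = cseq[ref_pos]
        if bs_strand == "+" and gbase == "C":
            ctx = cytosine_context(genome, chrom, ref_pos, "+")
            if ctx is None:
                continue
            if read_idx is None:
                status = "ambiguous"
            else:
                base = seq[read_idx]
                status = {"C": "methylated", "T": "unmethylated"}.get(base, "ambiguous")
            calls.append(MethylationCall(chrom, ref_pos, "+", ctx, status, getattr(aln, "read_id", "")))
        elif bs_strand == "-" and gbase == "G":
            ctx = cytosine_context(genome, chrom, ref_pos, "-")
            if ctx is None:
                continue
            if read_idx is None:
                status = "ambiguous"
            else:
                base = seq[read_idx]
                status = {"G": "methylated", "A": "unmethylated"}.get(base, "ambiguous")
            calls.append(MethylationCall(chrom, ref_pos, "-", ctx, status, getattr(aln, "read_id", "")))
    return calls


def methylation_string(aln, seq: str, genome: ReferenceGenome) -> str:
    """Per-read XM-style string: one character per read base.

    '.' for non-cytosine positions, z/Z x/X h/H for un/methylated
    CpG/CHG/CHH cytosines; ambiguous or context-less cytosines stay '.'.
    """
    out = ["."] * len(seq)
    chrom = aln.chromosome
    cseq = genome.sequences[chrom]
    for ref_pos, read_idx in _aligned_pairs(aln.cigar, aln.local_position):
        if read_idx is None:
            continue
        gbase = cseq[ref_pos]
        if (aln.strand == "+" and gbase != "C") or (aln.strand == "-" and gbase != "G"):
            continue
        ctx = cytosine_context(genome, chrom, ref_pos, aln.strand)
        if ctx is None:
            continue
        base = seq[read_idx]
        if aln.strand == "+":
            status = {"C": "methylated", "T": "unmethylated"}.get(base)
        else:
            status = {"G": "methylated", "A": "unmethylated"}.get(base)
        if status is not None:
            out[read_idx] = _XM_CHAR[(ctx, status)]
    return "".join(out)


def aggregate_report(calls: Iterable[MethylationCall]) -> pd.DataFrame:
    """Per-site summary: counts and methylation level.

    One row per (chromosome, position, strand, context) with columns
    count_M, count_U, count_ambiguous and level = M / (M + U) (NaN when
    no unambiguous call covers the site). Positions are 0-based here;
    the TSV writer emits 1-based.
    """
    rows = [
        (c.chromosome, c.genome_position, c.strand, c.context, c.status)
        for c in calls
    ]
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "context",
                     "count_M", "count_U", "count_ambiguous", "level"]
        )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "status"])
    pivot = (
        df.pivot_table(
            index=["chrom", "pos", "strand", "context"],
            columns="status", aggfunc="size", fill_value=0,
        )
        .reset_index()
    )
    for col, name in (
        ("methylated", "count_M"),
        ("unmethylated", "count_U"),
        ("ambiguous", "count_ambiguous"),
    ):
        pivot[name] = pivot[col] if col in pivot else 0
    denom = pivot["count_M"] + pivot["count_U"]
    pivot["level"] = pivot["count_M"] / denom.where(denom > 0)
    out = pivot[["chrom", "pos", "strand", "context",
                 "count_M", "count_U", "count_ambiguous", "level"]]
    return out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


class ReportAccumulator:
    """Streaming per-site counts, avoiding per-call object retention."""

    def __init__(self) -> None:
        self._counts: dict[tuple, list[int]] = {}

    def add(self, calls: Iterable[MethylationCall]) -> None:
        for c in calls:
            key = (c.chromosome, c.genome_position, c.strand, c.context)
            row = self._counts.setdefault(key, [0, 0, 0])
            if c.status == "methylated":
                row[0] += 1
            elif c.status == "unmethylated":
                row[1] += 1
            else:
                row[2] += 1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, pos, strand, ctx, m, u, a, (m / (m + u)) if m + u else float("nan"))
            for (chrom, pos, strand, ctx), (m, u, a) in self._counts.items()
        ]
        df = pd.DataFrame(
            rows,
            columns=["chrom", "pos", "strand", "context",
                     "count_M", "count_U", "count_ambiguous", "level"],
        )
        return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def write_cytosine_report(report: pd.DataFrame, path) -> None:
    """Write the Bismark-like tab-separated cytosine report (1-based)."""
    out = report.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)
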