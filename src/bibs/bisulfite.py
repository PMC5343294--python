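"""Bisulfite-converted genome texts and their four FM-indexes.

Directional (two-strand) protocol: a read is fully C→T converted and
searched (a) in original orientation against the C→T-converted genome
(original-top strand, OT) and (b) as its reverse complement against the
G→A-converted genome (original-bottom strand, OB). Reversed-text
indexes of both converted genomes support forward extension from the
read start. The unconverted genome is retained for Smith-Waterman
windows' coordinates and for methylation calling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from bibs.fmindex import FMIndex, build_fm_index, encode
from bibs.genome import ReferenceGenome

_META_MAGIC = "BIBS-INDEXSET-1"

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")


def ct_convert(seq: str) -> str:
    """C→T conversion (what full bisulfite conversion does to a read)."""
    return seq.translate(_CT)


def ga_convert(seq: str) -> str:
    """G→A conversion (the bottom-strand mirror of C→T)."""
    return seq.translate(_GA)


@dataclass
class BisulfiteIndexSet:
    """FM-indexes over both converted genome texts and their reversals."""

    ct_index: FMIndex
    ga_index: FMIndex
    ct_index_rev: FMIndex
    ga_index_rev: FMIndex
    genome: ReferenceGenome
    ct_text: np.ndarray  # encoded converted concatenated genome
    ga_text: np.ndarray

    def for_strand(self, strand: str) -> tuple[FMIndex, FMIndex, np.ndarray]:
        """(forward index, reversed-text index, converted text) for a strand.

        '+' selects the C→T pair (OT), '-' the G→A pair (OB).
        """
        if strand == "+":
            return self.ct_index, self.ct_index_rev, self.ct_text
        if strand == "-":
            return self.ga_index, self.ga_index_rev, self.ga_text
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ct_index.save(outdir / "ct.npz")
        self.ga_index.save(outdir / "ga.npz")
        self.ct_index_rev.save(outdir / "ct_rev.npz")
        self.ga_index_rev.save(outdir / "ga_rev.npz")
        meta = {
            "magic": _META_MAGIC,
            "chromosomes": {n: len(s) for n, s in self.genome.sequences.items()},
        }
        (outdir / "meta.json").write_text(json.dumps(meta))
        # genome stored as plain FASTA so the set is self-contained
        with open(outdir / "genome.fa", "w") as fh:
            for name, seq in self.genome.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    @classmethod
    def load(cls, indir: str | Path) -> "BisulfiteIndexSet":
        from bibs.genome import load_fasta

        indir = Path(indir)
        meta_path = indir / "meta.json"
        if not meta_path.exists():
            raise FileNotFoundError(f"{indir}: not a bibs index directory")
        meta = json.loads(meta_path.read_text())
        if meta.get("magic") != _META_MAGIC:
            raise ValueError(f"{indir}: unrecognized index format")
        genome = load_fasta(indir / "genome.fa")
        concat = genome.concatenated()
        return cls(
            ct_index=FMIndex.load(indir / "ct.npz"),
            ga_index=FMIndex.load(indir / "ga.npz"),
            ct_index_rev=FMIndex.load(indir / "ct_rev.npz"),
            ga_index_rev=FMIndex.load(indir / "ga_rev.npz"),
            genome=genome,
            ct_text=encode(ct_convert(concat)),
            ga_text=encode(ga_convert(concat)),
        )


def build_bisulfite_indexes(
    genome: ReferenceGenome, occ_stride: int = 64, sa_stride: int = 8
) -> BisulfiteIndexSet:
    """Build the four FM-indexes for a reference genome.

    Converted texts have the same length as the original; the C→T text
    contains no C and the G→A text no G.
    """
    concat = genome.concatenated()
    ct = encode(ct_convert(concat))
    ga = encode(ga_convert(concat))
    return BisulfiteIndexSet(
        ct_index=build_fm_index(ct, occ_stride, sa_stride),
        ga_index=build_fm_index(ga, occ_stride, sa_stride),
        ct_index_rev=build_fm_index(ct[::-1].copy(), occ_stride, sa_stride),
        ga_index_rev=build_fm_index(ga[::-1].copy(), occ_stride, sa_stride),
        genome=genome,
        ct_text=ct,
        ga_text=ga,
    )


def bisulfite_convert(genome: ReferenceGenome, **kwargs) -> BisulfiteIndexSet:
    """Alias for :func:`build_bisulfite_indexes`."""
    return build_bisulfite_indexes(genome, **kwargs)
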