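"""Reference genome container and FASTA loading.

Coordinates are 0-based, half-open everywhere in this package; the SAM
writer converts to 1-based at the output boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """An in-memory reference: chromosome name -> uppercase ACGTN string.

    ``offsets`` give each chromosome's start in the concatenated text so
    that global and (chromosome, local) coordinates convert both ways.
    """

    sequences: dict[str, str]
    offsets: dict[str, int] = field(init=False)
    total_length: int = field(init=False)

    def __post_init__(self) -> None:
        self.offsets = {}
        pos = 0
        for name, seq in self.sequences.items():
            self.offsets[name] = pos
            pos += len(seq)
        self.total_length = pos
        self._names = list(self.sequences)
        self._starts = [self.offsets[n] for n in self._names]

    def concatenated(self) -> str:
        """All chromosomes joined in declaration order."""
        return "".join(self.sequences.values())

    def to_global(self, chrom: str, pos: int) -> int:
        if not 0 <= pos <= len(self.sequences[chrom]):
            raise ValueError(f"position {pos} outside {chrom}")
        return self.offsets[chrom] + pos

    def to_local(self, gpos: int) -> tuple[str, int]:
        """Global concatenated-text coordinate -> (chromosome, local)."""
        if not 0 <= gpos < self.total_length:
            raise ValueError(f"global position {gpos} out of range")
        # linear scan is fine: genomes here have few chromosomes
        for name in reversed(self._names):
            start = self.offsets[name]
            if gpos >= start:
                return name, gpos - start
        raise ValueError(f"global position {gpos} out of range")

    def chrom_of(self, gpos: int) -> str:
        return self.to_local(gpos)[0]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        return seq[max(0, start):min(len(seq), end)]


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


def load_fasta(path: str | Path) -> ReferenceGenome:
    """Load a (multi-)FASTA file into a :class:`ReferenceGenome`.

    Lowercase bases are uppercased; any symbol outside {A,C,G,T,N} is
    mapped to N. Wrapped and unwrapped sequence lines are both accepted.
    """
    path = Path(path)
    sequences: dict[str, list[str]] = {}
    current: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FastaError(f"{path}:{lineno}: empty record name")
                if name in sequences:
                    raise FastaError(f"{path}:{lineno}: duplicate record {name!r}")
                current = sequences.setdefault(name, [])
            else:
                if current is None:
                    raise FastaError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                current.append(_NON_ACGTN.sub("N", line.upper()))
    if not sequences:
        raise FastaError(f"{path}: no FASTA records found")
    return ReferenceGenome({name: "".join(parts) for name, parts in sequences.items()})
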