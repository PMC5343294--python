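"""Synthetic bisulfite reads with known truth, and sensitivity scoring.

Reads are fixed-length fragments drawn uniformly from either strand of
a reference, mutated per base at a configurable rate (substitutions :
insertions : deletions = 80:10:10), then bisulfite-converted: every
cytosine of the pre-conversion read draws a methylation state from a
per-context profile and unmethylated cytosines become T. The truth
table records the origin, the applied edits and the methylation states,
so alignments can be scored as correctly (R) or wrongly (W) placed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bibs.genome import ReferenceGenome, revcomp

_BASES = "ACGT"

#: mammalian-like default: CpG mostly methylated, CHG/CHH almost never
DEFAULT_METH_PROFILE = {"CpG": 0.7, "CHG": 0.02, "CHH": 0.02}

#: edit-type mix among mutated bases
_EDIT_PROBS = {"sub": 0.8, "ins": 0.1, "del": 0.1}


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str       # post-conversion, as sequenced
    chromosome: str
    start: int          # leftmost 0-based reference coordinate
    strand: str
    ref_length: int     # reference bases consumed
    edits: list[tuple[int, str, str]]  # (read offset, sub|ins|del, base)
    meth_states: list[tuple[int, str, bool]]  # (read offset, context, methylated)


def random_genome(
    length: int, seed: int = 0, name: str = "chr1", gc: float = 0.41
) -> ReferenceGenome:
    """A seeded random single-chromosome genome (test fixture source)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])
    return ReferenceGenome({name: seq})


def _read_context(read: list[str], i: int) -> str:
    """Context of read cytosine i from the read's own next two bases."""
    n1 = read[i + 1] if i + 1 < len(read) else "A"
    if n1 == "G":
        return "CpG"
    n2 = read[i + 2] if i + 2 < len(read) else "A"
    return "CHG" if n2 == "G" else "CHH"


def _mutate(oriented: str, read_len: int, mut_rate: float, rng) -> tuple[list[str], list, int]:
    """Emit read_len bases from the oriented template with per-base edits."""
    out: list[str] = []
    edits: list[tuple[int, str, str]] = []
    i = 0
    while len(out) < read_len:
        if i >= len(oriented):
            raise ValueError("template exhausted; margin too small")
        if mut_rate > 0 and rng.random() < mut_rate:
            u = rng.random()
            if u < _EDIT_PROBS["sub"]:
                orig = oriented[i]
                b = _BASES[(  _BASES.index(orig) + 1 + rng.integers(3)) % 4] \
                    if orig in _BASES else _BASES[rng.integers(4)]
                out.append(b)
                edits.append((len(out) - 1, "sub", b))
                i += 1
            elif u < _EDIT_PROBS["sub"] + _EDIT_PROBS["ins"]:
                b = _BASES[rng.integers(4)]
                out.append(b)
                edits.append((len(out) - 1, "ins", b))
            else:
                edits.append((len(out), "del", oriented[i]))
                i += 1
        else:
            out.append(oriented[i])
            i += 1
    return out, edits, i


def apply_edits(origin: str, edits: list[tuple[int, str, str]]) -> str:
    """Replay a truth table's edits onto the oriented origin substring.

    Edits are replayed in recorded order (offsets are non-decreasing by
    construction); the result is the pre-conversion read.
    """
    out: list[str] = []
    i = 0
    for off, kind, base in edits:
        while len(out) < off:
            out.append(origin[i])
            i += 1
        if kind == "sub":
            out.append(base)
            i += 1
        elif kind == "ins":
            out.append(base)
        else:  # del consumes an origin base without emitting
            i += 1
    out.extend(origin[i:])
    return "".join(out)


def simulate(
    genome: ReferenceGenome,
    n_reads: int,
    read_len: int,
    mut_rate: float = 0.01,
    meth_profile: dict[str, float] | None = None,
    rng_seed: int = 0,
) -> list[SimulatedRead]:
    """Generate reads with known truth (deterministic for a fixed seed)."""
    if not 0 <= mut_rate < 1:
        raise ValueError("mut_rate must be in [0, 1)")
    meth_profile = DEFAULT_METH_PROFILE if meth_profile is None else meth_profile
    rng = np.random.default_rng(rng_seed)
    margin = max(10, read_len // 10)
    chroms = list(genome.sequences)
    lengths = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    if (lengths < read_len + margin).any():
        raise ValueError(f"read_len {read_len} exceeds a chromosome length")
    weights = lengths / lengths.sum()

    reads: list[SimulatedRead] = []
    for k in range(n_reads):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        seq = genome.sequences[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        span = read_len + margin
        if strand == "+":
            a = int(rng.integers(0, len(seq) - span + 1))
            oriented = seq[a:a + span]
        else:
            r = int(rng.integers(span, len(seq) + 1))
            oriented = revcomp(seq[r - span:r])
        pre, edits, consumed = _mutate(oriented, read_len, mut_rate, rng)
        start = a if strand == "+" else r - consumed

        meth_states: list[tuple[int, str, bool]] = []
        post = list(pre)
        for i, b in enumerate(pre):
            if b != "C":
                continue
            ctx = _read_context(pre, i)
            methylated = bool(rng.random() < meth_profile.get(ctx, 0.0))
            meth_states.append((i, ctx, methylated))
            if not methylated:
                post[i] = "T"
        reads.append(
            SimulatedRead(
                read_id=f"sim{k}",
                sequence="".join(post),
                chromosome=chrom,
                start=start,
                strand=strand,
                ref_length=consumed,
                edits=edits,
                meth_states=meth_states,
            )
        )
    return reads


def truth_table(reads: list[SimulatedRead]) -> pd.DataFrame:
    """Tab-friendly truth: one row per read.

    ``edits`` is ';'-joined 'offset:kind:base'; ``meth`` is ';'-joined
    'offset:context:0|1'.
    """
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "chromosome": [r.chromosome for r in reads],
            "start": [r.start for r in reads],
            "strand": [r.strand for r in reads],
            "ref_length": [r.ref_length for r in reads],
            "edits": [";".join(f"{o}:{k}:{b}" for o, k, b in r.edits) for r in reads],
            "meth": [
                ";".join(f"{o}:{c}:{int(m)}" for o, c, m in r.meth_states)
                for r in reads
            ],
        }
    )


def write_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def evaluate(
    sam_path,
    truth: pd.DataFrame,
    tolerance: int = 5,
) -> dict[str, float]:
    """Score primary alignments against the truth table.

    R = % of reads placed within ±tolerance of the true origin on the
    correct chromosome and strand; W = % aligned elsewhere; the
    remainder is unaligned. Duplicate primary records are an error.
    """
    import pysam

    by_id = truth.set_index("read_id")
    seen: set[str] = set()
    correct = 0
    wrong = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name in seen:
                raise ValueError(f"duplicate primary alignment for {rec.query_name}")
            seen.add(rec.query_name)
            if rec.is_unmapped:
                continue
            row = by_id.loc[rec.query_name]
            strand = "-" if rec.is_reverse else "+"
            if (
                rec.reference_name == row["chromosome"]
                and strand == row["strand"]
                and abs(rec.reference_start - row["start"]) <= tolerance
            ):
                correct += 1
            else:
                wrong += 1
    n = len(truth)
    return {
        "n": n,
        "R": 100.0 * correct / n if n else 0.0,
        "W": 100.0 * wrong / n if n else 0.0,
        "unaligned": 100.0 * (n - correct - wrong) / n if n else 0.0,
    }
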