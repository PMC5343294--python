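"""Per-read stage orchestration: BWT -> seeding -> CALs -> SW -> calls.

Every read follows the same stage order: one bidirectional full-read
attempt; on failure, iterative inner-segment seeding; seed grouping
into CALs; Smith-Waterman gap filling inside the top-ranked CALs; best
alignment selection; methylation calling. Reads are independent work
units, so any parallel schedule must reproduce the single-worker
output — records are emitted in input order regardless of workers.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from bibs.bisulfite import BisulfiteIndexSet, ct_convert, ga_convert
from bibs.cal import build_cals
from bibs.fmindex import encode
from bibs.genome import revcomp
from bibs.io import make_sam_record, read_fastq, sam_header
from bibs.methylation import ReportAccumulator, call_methylation, methylation_string, write_cytosine_report
from bibs.search import SearchBudget, iterative_seed
from bibs.sw import (
    Alignment,
    InconsistentSeedGeometry,
    ScoringScheme,
    align_read_in_window,
    fill_and_assemble,
    pick_best,
)

#: cap on materialized full-read BWT hits turned into candidate alignments
MAX_FULL_HITS = 10


@dataclass
class PipelineConfig:
    eid_budget: int = 2
    budget_split: tuple[int, int] | None = None  # (backward, forward)
    min_inner_len: int = 15
    single_seed_min_len: int = 30
    cal_cap: int = 20
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    min_identity: float = 0.80
    directional: bool = True
    workers: int = 1

    def __post_init__(self) -> None:
        if self.min_inner_len < 1 or self.single_seed_min_len < 1 or self.cal_cap < 1:
            raise ValueError("thresholds must be positive")
        if self.workers < 1:
            raise ValueError("worker count must be >= 1")

    @property
    def budget(self) -> SearchBudget:
        return SearchBudget(self.eid_budget, self.budget_split)


def auto_tune(read_len: int, **overrides) -> PipelineConfig:
    """Deterministic read-length-dependent defaults.

    min_inner_len = clamp(read_len/10, 15, 50); single_seed_min_len =
    max(30, read_len/4); two EIDs for reads of 100 nt and longer, one
    below. Explicit keyword overrides win.
    """
    if read_len < 20:
        raise ValueError("auto_tune requires read_len >= 20")
    params = dict(
        eid_budget=2 if read_len >= 100 else 1,
        min_inner_len=int(min(50, max(15, read_len / 10))),
        single_seed_min_len=max(30, read_len // 4),
    )
    params.update(overrides)
    return PipelineConfig(**params)


@dataclass
class StageRecord:
    """Per-read stage outcome and counters."""

    read_id: str
    outcome: str = "unmapped"  # bwt_full | seeded_sw | unmapped
    iterations: int = 0
    n_seeds: int = 0
    n_cals: int = 0
    sw_cells: int = 0
    expansions: int = 0


def _combos(seq: str, indexes: BisulfiteIndexSet, directional: bool):
    """(pattern, strand, fwd index, rev index, text) search combinations.

    Directional: the C->T read against the C->T genome ('+', OT) and
    its reverse complement against the G->A genome ('-', OB).
    Non-directional adds the two complementary-strand products.
    """
    ct_read = ct_convert(seq)
    out = [
        ("+", encode(ct_read), *indexes.for_strand("+")),
        ("-", encode(revcomp(ct_read)), *indexes.for_strand("-")),
    ]
    if not directional:
        ga_read = ga_convert(seq)
        out.append(("+", encode(ga_read), *indexes.for_strand("-")))
        out.append(("-", encode(revcomp(ga_read)), *indexes.for_strand("+")))
    return out


def align_read(
    read_id: str,
    seq: str,
    indexes: BisulfiteIndexSet,
    config: PipelineConfig,
) -> tuple[Alignment | None, StageRecord]:
    """Run the full stage pipeline on one read."""
    genome = indexes.genome
    record = StageRecord(read_id)
    budget = config.budget
    candidates: list[Alignment] = []
    pending_cals: list[tuple] = []  # (CAL, pattern, text) awaiting SW
    any_full = False

    def bounds_of(gpos: int) -> tuple[int, int]:
        chrom, _ = genome.to_local(gpos)
        start = genome.offsets[chrom]
        return start, start + len(genome.sequences[chrom])

    for strand, pattern, idx_fwd, idx_rev, text in _combos(
        seq, indexes, config.directional
    ):
        result = iterative_seed(
            idx_fwd, idx_rev, pattern, budget, config.min_inner_len
        )
        record.expansions += result.expansions

        if result.status == "fully_aligned":
            any_full = True
            hits = np.unique(result.full_hits)[:MAX_FULL_HITS]
            for pos in hits:
                pos = int(pos)
                if result.full_eids == 0:
                    aln = Alignment(
                        position=pos,
                        strand=strand,
                        cigar=f"{len(pattern)}M",
                        score=config.scheme.match * len(pattern),
                        edit_distance=0,
                        matches=len(pattern),
                    )
                else:
                    pad = budget.max_eids + 2
                    aln = align_read_in_window(
                        pattern, text,
                        max(0, pos - pad),
                        min(len(text), pos + len(pattern) + pad),
                        strand, config.scheme,
                    )
                candidates.append(aln)
            continue

        if result.status == "unseeded":
            continue

        record.iterations = max(
            record.iterations, max(s.iteration for s in result.seeds)
        )
        record.n_seeds += len(result.seeds)

        cals = build_cals(
            result.seeds,
            read_len=len(pattern),
            single_seed_min_len=config.single_seed_min_len,
            budget_eids=budget.max_eids,
            strand=strand,
            bounds_of=bounds_of,
        )
        record.n_cals += len(cals)
        pending_cals.extend((cal, pattern, text) for cal in cals)

    # per-read cap: the highest-ranked CALs across both strands proceed
    # to the SW stage; once two windows have been verified, weakly
    # supported leftovers cannot change the outcome and are skipped
    ranked = sorted(
        pending_cals,
        key=lambda ct: (-ct[0].n_seeds, -ct[0].covered_read,
                        ct[0].window_length, ct[0].window_start),
    )[: config.cal_cap]
    processed = 0
    for cal, pattern, text in ranked:
        if processed >= 2 and cal.n_seeds <= ranked[0][0].n_seeds // 2:
            break
        try:
            aln = fill_and_assemble(
                cal, pattern, text, config.scheme,
                min_identity=config.min_identity,
            )
        except InconsistentSeedGeometry:
            continue
        processed += 1
        if aln is not None:
            record.sw_cells += aln.sw_cells
            candidates.append(aln)

    if not candidates:
        return None, record
    best, _ = pick_best(candidates)
    chrom, local = genome.to_local(best.position)
    best.chromosome = chrom
    best.local_position = local
    record.outcome = "bwt_full" if any_full and best.sw_cells == 0 else "seeded_sw"
    return best, record


def _align_batch(args):
    reads, indexes, config = args
    return [align_read(rid, seq, indexes, config) for rid, seq, _ in reads]


def run_pipeline(
    fastq: str | Path,
    indexes: BisulfiteIndexSet | str | Path,
    config: PipelineConfig | None = None,
    out_sam: str | Path = "out.sam",
    out_report: str | Path | None = None,
    emit_xm: bool = False,
    log=sys.stderr,
) -> dict:
    """Align a FASTQ, write SAM (+ optional cytosine report), return stats.

    Every input read appears exactly once in the SAM, mapped or as an
    unmapped (flag 4) record, in input order.
    """
    if not isinstance(indexes, BisulfiteIndexSet):
        indexes = BisulfiteIndexSet.load(indexes)
    genome = indexes.genome
    reads = list(read_fastq(fastq))
    if config is None:
        config = auto_tune(len(reads[0][1])) if reads else PipelineConfig()

    if config.workers > 1 and len(reads) > 1:
        import multiprocessing as mp

        chunks = [
            (reads[i::config.workers], indexes, config)
            for i in range(config.workers)
        ]
        with mp.get_context("fork").Pool(config.workers) as pool:
            chunk_results = pool.map(_align_batch, chunks)
        results: list = [None] * len(reads)
        for w, chunk in enumerate(chunk_results):
            for k, res in enumerate(chunk):
                results[w + k * config.workers] = res
    else:
        results = [align_read(rid, seq, indexes, config) for rid, seq, _ in reads]

    header = sam_header(genome)
    accumulator = ReportAccumulator()
    stats = {"total": 0, "mapped": 0, "unmapped": 0,
             "bwt_full": 0, "seeded_sw": 0, "sw_cells": 0, "expansions": 0}
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as sam:
        for (rid, seq, qual), (aln, record) in zip(reads, results):
            stats["total"] += 1
            stats["sw_cells"] += record.sw_cells
            stats["expansions"] += record.expansions
            if aln is None:
                stats["unmapped"] += 1
                sam.write(make_sam_record(header, rid, seq, qual))
                continue
            stats["mapped"] += 1
            stats[record.outcome] += 1
            oriented = seq if aln.strand == "+" else revcomp(seq)
            if aln.strand == "-" and qual != "*":
                qual = qual[::-1]
            xm = None
            calls = call_methylation(aln, oriented, genome)
            accumulator.add(calls)
            if emit_xm:
                xm = methylation_string(aln, oriented, genome)
            sam.write(make_sam_record(header, rid, oriented, qual, aln, xm))
    if out_report is not None:
        write_cytosine_report(accumulator.to_frame(), out_report)
    if log is not None:
        print(
            f"[bibs] {stats['total']} reads: {stats['mapped']} mapped "
            f"({stats['bwt_full']} full-BWT, {stats['seeded_sw']} via seeding+SW), "
            f"{stats['unmapped']} unmapped; {stats['sw_cells']} SW cells",
            file=log,
        )
    stats["report"] = accumulator.to_frame()
    return stats
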