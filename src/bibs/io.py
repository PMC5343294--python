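"""FASTQ input and SAM output at the pipeline boundary."""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import pysam

from bibs.genome import ReferenceGenome


class FastqError(ValueError):
    pass


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a 4-line FASTQ.

    CRLF line endings are tolerated; a quality line of '*' is accepted
    (qualities are unused downstream). Malformed records raise
    :class:`FastqError` naming the record number.
    """
    with open(path) as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\r\n")
            if not header:
                continue
            record += 1
            if not header.startswith("@"):
                raise FastqError(f"record {record}: header {header[:30]!r} lacks '@'")
            seq = fh.readline().rstrip("\r\n")
            plus = fh.readline().rstrip("\r\n")
            qual = fh.readline().rstrip("\r\n")
            if not plus.startswith("+"):
                raise FastqError(f"record {record}: separator line missing")
            if not seq:
                raise FastqError(f"record {record}: empty sequence")
            if qual != "*" and len(qual) != len(seq):
                raise FastqError(
                    f"record {record}: quality length {len(qual)} != sequence {len(seq)}"
                )
            yield header[1:].split()[0], seq.upper(), qual


def sam_header(genome: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in genome.sequences.items()
            ],
            "PG": [{"ID": "bibs", "PN": "bibs", "VN": "0.1.0"}],
        }
    )


def make_sam_record(
    header: pysam.AlignmentHeader,
    read_id: str,
    seq: str,
    qual: str,
    aln=None,
    xm: str | None = None,
) -> pysam.AlignedSegment:
    """Build one primary SAM record (unmapped when aln is None).

    ``seq`` must already be in reference orientation for mapped
    reverse-strand alignments.
    """
    rec = pysam.AlignedSegment(header)
    rec.query_name = read_id
    rec.query_sequence = seq
    rec.query_qualities = None if qual == "*" else pysam.qualitystring_to_array(qual)
    if aln is None:
        rec.is_unmapped = True
        rec.mapping_quality = 0
        return rec
    rec.flag = 16 if aln.strand == "-" else 0
    rec.reference_name = aln.chromosome
    rec.reference_start = aln.local_position
    rec.mapping_quality = aln.mapq
    rec.cigarstring = aln.cigar
    tags = [("NM", aln.edit_distance), ("AS", aln.score), ("XB", aln.bisulfite_strand_tag)]
    if xm is not None:
        tags.append(("XM", xm))
    rec.set_tags(tags)
    return rec
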