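"""Build bisulfite FM-indexes and run a bidirectional search by hand.

Shows the two converted search spaces (OT and OB) and how an exact
read is fully aligned by the BWT stage without any dynamic programming.
"""

from bibs import SearchBudget, bidirectional_align, build_bisulfite_indexes, random_genome
from bibs.bisulfite import ct_convert
from bibs.fmindex import encode
from bibs.genome import revcomp

genome = random_genome(100_000, seed=7)
indexes = build_bisulfite_indexes(genome)

# a perfect OT-strand read: drawn from the top strand, fully converted
fragment = genome.sequences["chr1"][25_000:25_150]
ot_read = ct_convert(fragment)  # what the sequencer delivers (all C unmethylated)

fwd, rev, _ = indexes.for_strand("+")
res = bidirectional_align(fwd, rev, encode(ct_convert(ot_read)), SearchBudget(2))
print("OT status:", res.status)           # fully_aligned: BWT alone placed it
print("genome position:", res.full_hits)  # 25000 == the true origin
print("edits spent:", res.full_eids)

# an OB-strand read comes from the bottom strand; its reverse
# complement is searched against the G->A index
ob_read = ct_convert(revcomp(fragment))
ob_pattern = encode(revcomp(ct_convert(ob_read)))
fwd, rev, _ = indexes.for_strand("-")
res = bidirectional_align(fwd, rev, ob_pattern, SearchBudget(2))
print("OB status:", res.status, "at", res.full_hits)  # same origin, flag 16 in SAM
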