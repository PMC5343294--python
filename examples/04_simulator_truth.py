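"""The simulator's truth table and its round-trip guarantee.

Every read records its origin, the exact edits applied and the drawn
methylation states; replaying the edits onto the origin substring
reproduces the pre-conversion read.
"""

from bibs import random_genome, simulate
from bibs.genome import revcomp
from bibs.simulate import apply_edits, truth_table

genome = random_genome(100_000, seed=2)
reads = simulate(genome, 5, 100, mut_rate=0.05, rng_seed=9)

print(truth_table(reads)[["read_id", "chromosome", "start", "strand", "edits"]])
seq = genome.sequences["chr1"]
for r in reads:
    frag = seq[r.start:r.start + r.ref_length]
    oriented = frag if r.strand == "+" else revcomp(frag)
    pre = apply_edits(oriented, r.edits)
    # pre-conversion read differs from the sequenced read only at
    # converted (unmethylated) cytosines
    diffs = [(a, b) for a, b in zip(pre, r.sequence) if a != b]
    assert all(a == "C" and b == "T" for a, b in diffs)
    print(f"{r.read_id}: {len(r.edits)} edits, {len(diffs)} converted cytosines")
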