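"""Watch iterative seeding bracket mutations and form CALs.

A read with two substitutions cannot be finished by the bidirectional
BWT pass; the iterative loop emits seeds around each mutated base and
the CAL builder groups them into one candidate window.
"""

from bibs import SearchBudget, build_cals, build_bisulfite_indexes, iterative_seed, random_genome, rank_cals
from bibs.bisulfite import ct_convert
from bibs.fmindex import encode

genome = random_genome(200_000, seed=3)
indexes = build_bisulfite_indexes(genome)

read = list(ct_convert(genome.sequences["chr1"][50_000:50_300]))
for pos in (100, 200):
    read[pos] = {"A": "G", "G": "T", "T": "A", "C": "G"}[read[pos]]
pattern = encode("".join(read))

fwd, rev, _ = indexes.for_strand("+")
result = iterative_seed(fwd, rev, pattern, SearchBudget(0), min_inner_len=15)
print("status:", result.status)
for s in result.seeds:
    print(f"  iter {s.iteration} {s.direction:8s} read[{s.read_start}:{s.read_end}) "
          f"-> genome {s.genome_starts.tolist()} (eids {s.eids_used})")

cals = rank_cals(build_cals(result.seeds, read_len=300))
print(f"{len(cals)} CAL(s); best window {cals[0].window_start}-{cals[0].window_end} "
      f"with {cals[0].n_seeds} seeds covering {cals[0].covered_read} read bases")
# the window contains the true origin 50000 and is barely longer than the read
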