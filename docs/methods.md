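# Methods

## Model and assumptions

`bibs` aligns single-end reads from directional (two-strand) bisulfite
libraries. All searching and gap filling happen in fully converted
space: the read is C→T converted once and compared, in original
orientation, against the C→T-converted genome (original-top strand,
OT), and as its reverse complement against the G→A-converted genome
(original-bottom strand, OB). Working fully converted makes a
bisulfite T-over-C (or A-over-G) a literal match, so the aligner
itself is methylation-blind and symmetric; the original read and
genome are consulted only by the methylation caller. A
`--non-directional` flag adds the two complementary-product
combinations (G→A read against the G→A index and its reverse
complement against the C→T index); methylation calls are emitted only
from OT/OB alignments, where the C/T readout is defined.

The genome alphabet is {A,C,G,T,N}. N is indexed as a literal fifth
symbol but a read symbol never matches it (and a read N never matches
anything), so assembly gaps cannot seed alignments; an N can only be
crossed by spending an edit.

## Search stage

Each converted genome text carries an FM-index (BWT via numpy
prefix-doubling suffix-array construction, cumulative-count array,
rank checkpoints every 64 symbols, suffix-array samples every 8 text
positions; both strides configurable) plus an index of the reversed
text so that extension can run from either read end.

Extension is exact until the occurrence interval would become empty.
While the per-direction edit budget lasts, the search then branches —
substitutions first, then deletions, then insertions — at the failure
symbol or at any matched symbol up to 16 positions back
(`BACKTRACK_WINDOW`). The backtrack matters because an exact match can
coast past a true edit on a chance occurrence elsewhere; on random
genome-scale texts such spurious runs are about log_σ(genome length)
symbols, well under 16 even for gigabase genomes. Among all maximal
extensions the longest wins, ties by fewer edits, then by branch
order. The total budget (0, 1 or 2) is split between the directions —
1+1 by default for budget 2, which is what keeps the search tree from
squaring; a 2+0 split is available.

A full-read alignment is declared when either extension covers the
whole segment, or the two extensions touch/overlap and some pair of
their genome placements agrees with the read-implied distance within
the edit budget. Otherwise the two seeds' inner limits bound the
unaligned inner segment, which is re-seeded after shrinking by one
base at each end (the two failure symbols, which by construction
cannot extend at the adjacent locus). Iteration stops below
`min_inner_len` (default 15 nt; at that length the expected number of
chance placements in converted space stays below one for genomes up to
roughly a gigabase) or when a pass yields no seed.

Occurrence intervals larger than 500 are kept but flagged
low-specificity; such seeds may join groups but cannot form a
candidate window alone.

## CAL formation

A Candidate Alignment Location is a genome window in which the whole
read is then verified. Rule A: one seed longer than
`single_seed_min_len` (default max(30, read_len/4)). Rule B: a maximal
group of ≥ 2 collinear seeds — read order equals genome order,
non-overlapping read intervals, genome span (seed lengths included)
under read_len + 2·budget + max(8, read_len/100). The last term
allows ~1% indel drift; without it, long reads carrying several
deletions lose their true group. Both group constraints are pairwise,
so maximal groups are exactly the maximal cliques of the compatibility
graph; they are enumerated with Bron-Kerbosch per connected component
after sorting placements by genome position (the graph is local, so
components stay small). Consecutive seeds may overlap on the genome by
up to the edit budget — edit branching can misplace an indel by a base
at a seed edge — and assembly handles that case with a single banded
whole-window alignment instead of gap splicing.

Windows are sized so the full read plus padding fits
(read_len + 2·(budget + 8) + read_len/100), clipped at chromosome
bounds; near-duplicate windows (starts within 8 nt) merge. CALs rank
by member count, then total read coverage, then window compactness;
the top 20 per read (across both strands) proceed to verification, and
once two windows have been verified, remaining CALs with at most half
the top seed support are skipped — they cannot win the final
selection.

## Gap filling and assembly

Seed blocks enter the CIGAR directly from the search stage's recorded
edits. Each inter-seed gap is aligned by affine-gap local
Smith-Waterman of the read gap against the corresponding genome
sub-window, spliced so the counts stay exact; terminal flanks use a
fitting alignment anchored at the outermost seed, and flanks that
align at under 50% identity are soft-clipped. Two kernel layouts
exist: full-matrix, and banded storage (column = j − i + band) used
whenever the band is narrower than the matrix; gap bands cover the
ref/read length difference plus 32, since a genuine inter-seed gap is
near-diagonal.

Scores default to match +5, mismatch −4, gap open −10, gap extend −2.
The extend penalty is deliberately not cheaper: with extend −1 an
8-base terminal deletion reaching a 2-base chance match outscores two
honest substitutions by one point and drags the reported leftmost
coordinate off the origin.

A CAL is rejected when a gap of ≥ 16 nt scores below 60% of its
maximum (shorter gaps — typically one mutated base — are policed by
the global filter instead) or when assembled matches fall below 80% of
the read length. The primary alignment is the highest score, ties by
lower edit distance then leftmost coordinate; MAPQ is 60 for a lone
candidate, otherwise min(60, 0.4 × score gap to the runner-up), 0 on
an exact tie. NM and AS are computed in converted space.

## Methylation calling

For every aligned genomic C on the OT strand (G on OB): read C → 
methylated, T → unmethylated (G/A mirrored on OB); any other base, or
a deletion, is ambiguous; soft-clipped cytosines are simply uncovered.
Context comes from the unconverted genome, strand-aware (for a
bottom-strand cytosine the two following bases run leftwards on the
complement); cytosines whose context window leaves the chromosome or
touches an N are skipped. The report is a Bismark-like TSV (chrom,
1-based pos, strand, context, count_M, count_U, count_ambiguous,
level with level = M/(M+U)), and an optional XM-style per-read tag
(z/Z, x/X, h/H) can be emitted in the SAM.

## Read simulator

The simulator draws uniform origins on either strand, emits
fixed-length reads with per-base mutations (substitution : insertion :
deletion = 80:10:10) at a configurable rate, then draws a methylation
state per read cytosine from a per-context profile (defaults CpG 0.7,
CHG 0.02, CHH 0.02 — mammalian-like) and converts unmethylated Cs to
T. Mutations precede conversion, so replaying the recorded edits onto
the origin substring reproduces the pre-conversion read exactly.
Contexts for the draw come from the read's own next two bases — equal
to the genomic context except at mutated or read-terminal cytosines,
so a read-final CpG can occasionally be treated as CHH and convert;
aggregate levels absorb this at the 10⁻³ scale. Qualities are constant
('I'); the aligner never reads them.

What the simulator does not model: quality-dependent sequencing error,
homopolymer artifacts, PCR duplicates, incomplete bisulfite
conversion, and real genome repeat structure. Passing sensitivity
tests on random genomes therefore bounds algorithmic loss (seeding,
grouping, assembly) but understates the multi-mapping ambiguity a
repeat-rich genome would add.

## Evaluation and problem sizes

Sensitivity is scored against the simulation truth: R = % of reads
whose primary alignment is within ±5 nt of the origin on the correct
chromosome and strand (indels shift leftmost coordinates, hence the
tolerance), W = % aligned elsewhere. The test suite runs its
end-to-end checks on a seeded 2 Mb random genome with 150–400 reads
per length; `scripts/acceptance.py` uses a 10 Mb genome with
500–2000 reads per length at 75–1600 nt — sizes chosen so the whole
validation completes in minutes on one CPU while keeping binomial
noise on the reported percentages below a few tenths of a percent.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally; SAM output is 1-based.
DP tie-breaks are fixed (best cell: smallest reference then read
index; path: diagonal > up > left), making every output deterministic
for a fixed input, including across worker counts (reads are
independent; records are emitted in input order). Empty FASTQ input
yields a header-only SAM and an empty report; unmapped reads are
always emitted with flag 4; an empty read segment scores 0 in the DP;
a read shorter than `min_inner_len` still gets its iteration-1 pass.

## Known limitations

Single-end only; no paired-end rescue. The per-direction edit budget
caps at 2, so dense edit clusters inside otherwise-unseedable short
reads can fail. MAPQ is a monotone surrogate from the score gap, not a
calibrated error probability. The index targets genomes up to ~100 Mb
in memory (plain arrays rather than succinct structures); a human-scale
genome would need a compressed rank/select layer.
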