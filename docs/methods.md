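# Methods

This note documents the model behind `repkit`, the parameters that
matter, the numerical and design choices where the design was open, and
what the synthetic benchmark does and does not demonstrate.

## Signal model

A repeat family with `c` copies and per-base divergence `d` contributes,
at each consensus position, a k-mer that is identical across
`X ~ Binomial(c, (1-d)^k)` copies. With read depth `D` and read length
`L`, a single-copy k-mer is covered by about `D * (L - k + 1) / L`
reads (the *base frequency*), so the conserved repeat k-mer is observed
about `X` times that. Frequency thresholds therefore translate directly
into "number of copies sharing the k-mer": the highly frequent cutoff
(`high_multiplier`, default 10) targets k-mers shared by at least that
many copies, and the intermediate floor (`mid_multiplier`, default 3)
bounds the zone where repeat-related k-mers can still be distinguished
from single-copy background.

The base frequency is estimated as the mode of the k-mer count histogram
after excluding bins below `min_count = 2` (the sequencing-error peak
sits at count 1-2). Depth and "average k-mer frequency" are deliberately
collapsed into this single user-overridable scalar: both cutoffs
multiply it, and on uniform-coverage data the histogram mode estimates
exactly the quantity the cutoffs need.

## Stage-by-stage choices

**Counting** (default `k = 30`). Canonical counting (a k-mer pools with
its reverse complement under the lexicographically smaller key) is the
default because reads sample both strands; forward-only counting is a
flag. Windows containing non-ACGT characters are skipped, not errors.
K-mers up to k = 31 use a vectorised 2-bit-packed path; longer k falls
back to a dictionary scan.

**Recruitment.** The reference behaviour is "keep an intermediate k-mer
if it has a high-scoring gapped alignment, with zero mismatch/gap
penalties, to some highly frequent k-mer". With match reward only, the
optimal alignment score is exactly the LCS length, so the contract is:
share one exact `seed_len`-mer (default 12) with a high k-mer, and reach
LCS >= `min_score` (default `k - 5`) against a seed-sharing candidate.
For one edit between two k-mers a shared seed always exists when
`seed_len <= (k-1)/2` (pigeonhole), so the seed filter cannot cause
misses in the regime the score threshold accepts. Alignments are per
k-mer pair; overlaps spanning two different high k-mers are not
considered. Iteration (`max_rounds`, default 1) recruits against the
union of high and previously recruited k-mers, making the recruited set
monotone in the round count. LCS is computed with the bit-parallel
algorithm (arbitrary-precision words), cross-checked in the tests
against a textbook dynamic program.

**Polishing.** All-pairs comparison of k-mers is infeasible, so each
trial's `h` sampled positions are shared by every k-mer and grouping is
realised by exact h-mer bucketing. For any *pair* of k-mers this
preserves the closed-form grouping probability exactly (substitution
case) while costing near-linear time. Pairs linked in any of the
`n_trials` trials are merged transitively (connected components);
whether the original formulation intends transitive closure is open, and
components were chosen because "grouped together" has no stable meaning
for overlapping pairs otherwise. Defaults: `h = min(15, k)`; `e = 1`
(one mismatch or indel tolerated — indel-shifted k-mers need no special
handling because a shifted word is simply a different k-mer compared
positionally); `n_trials` is the smallest count with grouping
probability >= 0.99 at the configured `(k, h, e)` (no fixed default is
prescribed anywhere, so the package derives it from the formula).
Voting ties take the lexicographically smallest base, for determinism.
Partitioned (map-reduce style) execution splits (trial, bucket) work
units by a deterministic key and pools the resulting links globally, so
the output is bit-identical for every partition count — this is asserted
by tests rather than assumed.

**Assembly.** A native unitig assembler: nodes are
`(assembly_k - 1)`-mers, edges the `assembly_k`-mers contained in the
input k-mers (both orientations for canonical tables), contigs the
maximal non-branching paths, reverse-complement duplicates collapsed.
`assembly_k` defaults to `k - 5` so single-base variants of polished
k-mers still co-assemble. Minimal cleanup only: short (< 2 x
assembly_k) dead-end branches whose every edge has support <= 1 are
pruned; there is no bubble popping or coverage-based filtering.

**Merging.** Greedy: repeatedly merge the contig pair with the longest
suffix-prefix overlap of length >= `min_overlap` (default 10) and at
most `max_overlap_mismatch` (default 1) mismatches, ties broken toward
fewer mismatches then forward orientation then contig id. Both
orientations of *both* contigs are considered — a junction between two
contig prefixes is only visible with the first contig flipped, and
omitting that case leaves reverse-complement-stored unitigs unmergeable.
Before and between merges, a contig that matches a window of a longer
contig with at most `max_overlap_mismatch` substitutions is absorbed:
such contigs are variant branches of the dominant path and would
otherwise derail the greedy overlap choice. Junction disagreements take
the base of the higher-mean-support contig, consistent with the
frequency-weighted voting philosophy. Output is filtered to
`min_output_len` (default `2k`). The exact "reliable overlap" thresholds
are declared package defaults, not derived quantities.

**Clustering.** Pairwise similarity is the LCS of the better orientation
pair divided by the length of the *shorter* sequence, so a fragment
clusters with its full-length parent; pairs strictly above
`sim_threshold` (default 0.85) are linked and clusters are union-find
components labelled by their longest member. The similarity measure and
normalisation are package choices — the underlying idea only fixes
"pairwise similarity above 0.85 plus union-find".

**Evaluation.** Local alignments (match +1, mismatch -1, gap open -2,
extend -1, via Biopython's `PairwiseAligner`) of each assembled repeat
against each library entry, both orientations; a hit needs identity
(matches / alignment columns) >= 0.85 over at least `min_hit_len = 30`
columns. The length floor exists because an unbounded local aligner
reports short perfect matches between unrelated sequences, which would
make the hit count meaningless. `N_h` uses matches divided by the *full*
entry length for a single best repeat (uncovered positions count as
mismatches), so a merged multi-contig reconstruction does not count —
only a single sequence can "fully construct" an entry. `C_avg` solves
weighted interval scheduling (weight = interval length) over the hit
intervals; `C_m` solves the same restricted to the intervals of the
longest hitting repeat, which guarantees `C_m <= C_avg`. Coordinates are
0-based half-open; abutting intervals do not overlap.

## The simulator

`simulate_genome` plants repeat families into a uniform-random
background: each copy is an independent mutation of the family consensus
(substitutions i.i.d. per base; indels started per base with equal
insert/delete probability and lengths uniform on `[1, indel_max_len]`),
placed at non-overlapping, non-nested uniform positions on a random
strand. `simulate_reads` draws `round(depth * |genome| / read_len)`
single-end reads with uniform starts, random strand and i.i.d.
substitution errors. Everything is deterministic given the seed.

What the simulator does *not* model: quality scores, paired ends,
coverage biases (GC, mappability), PCR duplicates, indel sequencing
errors, nested or tandemly arranged repeats, and repeat families related
to one another. Tests passing on this benchmark show the pipeline's
logic is correct and that the frequency/recruitment/polishing mechanism
works under the stated signal model; they do not certify performance on
real libraries, where divergence is non-uniform and families overlap.

## Benchmark problem sizes

The shipped property checks use desk-scale instances chosen so the full
suite runs in minutes: low-divergence recovery uses a 200 kb genome, one
500 bp family x 40 copies at 2% substitution divergence, 100 bp reads at
20x with 0.5% error; the high-divergence comparison uses 100 kb, 15
copies at 8% divergence, three replicates. For the high-divergence study
the defaults `k = 30`, 10x/3x are hopeless by design — the expected
number of copies sharing a 30-mer is `15 * 0.92^30 ~ 1.2`, i.e. no
frequency signal exists at that word length — so the study configuration
is derived from the signal model above: `k = 21` gives
`15 * 0.92^21 ~ 2.6` expected sharing copies, the high tier is set at
k-mers shared by >= 3 copies (`high_multiplier = 2.5`) and the
intermediate floor at 2 sharing copies (`mid_multiplier = 1.7`). Under
these conditions the full pipeline's `C_avg` exceeds the
recruitment-and-polishing-disabled baseline in most but not all
replicates: when a replicate's baseline already assembles cleanly, the
extra recruited k-mers mainly add variant branches and the non-
overlapping-coverage metric penalises the slightly overlapping fragments
they produce. The improvement claim is therefore checked as a
best-of-three property, not per replicate.

## Known limitations

- The unitig assembler performs no bubble popping; at high divergence,
  variant k-mers that escape polishing (each pair is grouped with
  probability >= 0.99, not 1) fragment contigs. Merging and fuzzy
  containment absorb most but not all of the damage.
- Greedy longest-overlap merging can join repeats that genuinely share
  long terminal sequence (e.g. related families); clustering downstream
  mitigates but does not undo such joins.
- `N_h`'s full-length identity uses a single best local alignment per
  orientation; a repeat hitting one entry in several disjoint places
  contributes only its best block.
- K-mer counting is in-memory; the package targets bacterial-to-small-
  eukaryote read sets or subsampled larger ones, not disk-based counting
  at mammalian scale.
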