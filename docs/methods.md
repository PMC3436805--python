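# Methods

svdelver discovers genomic structural variants (SVs) — deletions, tandem
duplications, inversions and reciprocal translocations — from short-read
paired-end sequencing by combining two complementary signals: abnormally
mapping read pairs, which localize a rearrangement to within roughly one
insert size, and split reads crossing the junction, which place the
breakpoints at single-nucleotide resolution. This note describes the model
behind each stage, the parameters that matter, what the built-in simulator
does and does not emulate, and the numerical conventions the
implementation commits to.

## Library model and discordant pairs

Each input BAM is treated as one sequencing library. The library profile —
median and standard deviation of the outer insert size (leftmost alignment
start to rightmost alignment end) and the modal pair orientation — is
estimated from the first 10,000 properly paired primary alignments
(configurable; a floor of 1,000 pairs is enforced, below which profiling
fails loudly rather than guessing). The discordance cutoff is
`insert_max = median + 3·SD`; the multiplier is exposed as `--mad-cutoff`.

A uniquely mapping pair (both mapping qualities ≥ `--map-qual`, default 1;
secondary, supplementary and duplicate alignments ignored) is normalized so
its lexicographically (chromosome, position)-smaller alignment comes
first, then classified by a partition of orientation/order/distance space
(for an FR library; RF libraries are handled by mirroring):

| signature | pattern (normalized) |
|---|---|
| DEL | `+ −`, insert > insert_max |
| DUP | `− +` (everted order) |
| INV left / right | `+ +` / `− −` |
| TRA_1..4 | different chromosomes, keyed by the strand pair |

Anything else is concordant. Because insert sizes are approximately
normal, about 0.13% of perfectly ordinary fragments exceed the 3·SD
cutoff; these tail pairs are an irreducible noise floor of the paired-end
stage (see "Expected noise" below).

## Variant graph and clique clustering

Per signature class and chromosome (pair), position-sorted discordant
pairs become nodes of an undirected weighted graph. Two pairs are joined
when their left starts and their right ends each differ by at most the
expected insert range (the larger `insert_max` when the pairs come from
different libraries — a choice the mixed-library case forces; the window
could alternatively be `median ± 3·SD`, which is narrower on the left).
Intrachromosomal edge weights are the absolute difference of the
library-adjusted predicted SV sizes (outer span minus library median);
translocation edges use the sum of the absolute position differences on
both chromosomes. A line sweep builds the graph, abandoning the inner scan
once the left-gap exceeds the maximal range.

Each connected component contributes one cluster: starting from the
smallest-weight edge, the clique grows greedily by the smallest-weight
incident edge whose node is adjacent to every member, until no such node
exists. Ties break toward the smaller node id (input order) for
determinism. Singletons are discarded, so the minimum support is 2
(`--min-pairs`). Only one clique per component is reported; enumerating
all maximal cliques (which would separate same-type events sharing an
endpoint) is out of scope.

Cluster coordinates take the innermost member coordinate on each
breakpoint side: for deletions `[max upstream read end, min downstream
read start)`; duplications use the outermost mirror image
`[min a_start, max b_end)`; left-spanning inversions `[max a_end, max
b_end)`, right-spanning `[min a_start, min b_start)`; translocations take
one coordinate per chromosome by the same approach-side rule. Degenerate
estimates (start ≥ end) are dropped.

## Split-read refinement

Candidate split reads are the unmapped mates of single-anchored pairs
(optionally also soft-clipped reads). The anchor's strand and the library
orientation imply a window where the mate — and hence the junction — must
lie; the literal reading "anchor within 2·SD of the breakpoint" cannot
hold at the default geometry (the junction sits inside the *mate*, an
insert-minus-read-length away from the anchor's end), so the window used
is the mate's expected span widened by 2·SD: for a forward anchor,
breakpoints in `[anchor_end − 2σ, anchor_start + insert_max + 2σ]`. Each
candidate is assigned to the closest in-window breakpoint (ties to the
lower coordinate) and each call keeps at most L = 1000 candidates.

For every candidate call a local SV reference is extracted with a flanking
window of `insert_max` per side and rearranged into deletion-type
geometry, so that one junction appears as a prefix/suffix split in
consistent orientation: deletions are a plain extraction of the interval
plus flanks; duplications place the end-side segment before the
start-side one; inversions reverse-complement one side (built separately
for left- and right-spanning calls); translocations combine order and
strand changes according to the orientation class. A segment map
back-translates any position in the concatenation to a unique genomic
coordinate.

The enforced alignment direction of each candidate is resolved in
*rearranged-reference space*: the mate must align opposite to the anchor
there, so the raw sequence is reverse-complemented iff the anchor's
effective strand (BAM strand, flipped when the anchor falls in a
reverse-complemented segment) is forward. K-mer counting then runs on that
single orientation only.

K-mer filtering uses k = 7 against an index of the SV reference; each read
k-mer hit is normalized by its offset in the read, i.e. tallied per
alignment diagonal. K-mers containing N are skipped. Repeat-induced
multi-hits are resolved by processing diagonals in decreasing raw support
and flagging each k-mer as used once, so each k-mer supports one diagonal.
Diagonals with fewer than k_min = 3 hits are dropped; a read survives only
if at least two diagonals remain and the two most supported ones jointly
cover at least half of the read's k-mers (which bounds detectable
non-template insertions at half the read length). The offset between those
two diagonals, in index order, is the read's SV-length estimate. One
further check is needed that the construction implies but does not state:
the earlier read portion must sit on the *smaller* diagonal
(deletion-type order, verified via the mean k-mer offset per diagonal).
Junction reads originating from the complementary spanning side of an
inversion produce the mirrored pattern with the same unsigned offset and
would otherwise chimerize the consensus — in testing this single check
took split-read inversion recovery from ~50% to 100%.

Offsets are voted across reads (the per-read search is unbiased; only
ties break toward the paired-end predicted size, then the smaller offset).
With at least `--min-split` = 2 supporting reads, a gapless consensus is
built by per-column majority vote over the reads placed at their prefix
diagonals; column ties take the lowest-indexed read's base, edge columns
without coverage are trimmed, and an internal coverage gap voids the
refinement.

The consensus is split-aligned by double dynamic programming: two
affine-gap (Gotoh) scoring passes (match +5, mismatch −4, gap open −10,
gap extend −1; a gap of length L costs open + (L−1)·extend; all four
exposed as options) yield `f_i`, the best score of fitting the consensus
prefix `c[1..i]` anywhere in the reference, and `r_j`, the same for the
suffix `c[j..n]`. The optimal split maximizes `f_i + r_j` over `j ≥ i+1`
with each side keeping at least k bases; `j > i+1` leaves a non-template
microinsertion (capped at half the consensus). The kernels are
numba-compiled and keep O(reference) memory. On a clean junction the split
is slid left through any shared sequence and the tract length is reported
as microhomology; exactly one of {microinsertion, microhomology, clean
junction} holds. The consensus alignment quality is the identity fraction
of the gapless prefix/suffix placement (floor 0.8, configurable);
breakpoints are translated back through the segment map.

A refinement is accepted only if the split-read SV length confirms the
paired-end length within c = 10%. Interchromosomal junctions have no
defined length, so translocations instead require both split-read
breakpoints within `insert_max` of the paired-end estimates. Any stage
failure degrades gracefully to the imprecise paired-end call.

## Merging and output

Inversions are called separately per spanning side; complementing left/
right calls merge when their reciprocal overlap (intersection over the
longer interval) is at least 80%, best-first by the summed breakpoint
distance, each call merging at most once. Merged coordinates come from the
precise partner when exactly one side is refined, from the left partner
when both are, and from the midpoints when neither is. Translocation
junction calls merge when they share the chromosome pair, support
complementary orientation classes, and their predicted insertion positions
are less than z = 300 bp apart (strict), best-first by that distance;
the merged record carries the insertion point and both segment
boundaries. Merging unions support and never moves a precise breakpoint;
a second merge pass is a no-op.

Output is VCF 4.2 via pysam with symbolic ALTs (`<DEL>`, `<DUP>`, `<INV>`)
and breakend notation for translocations, using the padding-base
convention (POS is the base before the event, so INFO END equals the
0-based exclusive end), plus a flat 1-based TSV mirror. INFO carries
PE/SR support, mean mapping quality, consensus and its quality,
microinsertion sequence and microhomology length, confidence intervals
for imprecise calls, orientation class and merge provenance; records sort
deterministically. `PASS`/`LowQual` filters separate refined or
well-supported calls (≥3 pairs, mean mapq ≥ 20) from the rest. Genotype
likelihoods are out of scope.

## Synthetic data generator

The simulator emulates the benchmark design: a seeded uniform-random
reference (default 5 Mbp), non-overlapping planted events (default sizes
500–5000 bp) with a one-kilobase spacing/edge margin so clusters remain
attributable, FR pairs at 15× physical coverage with 75 bp reads, outer
inserts Normal(300, 30) truncated at twice the read length, and i.i.d.
substitution errors at 1% — these defaults *are* the study conditions and
are not adjusted per experiment. Deletions remove their segment from the
donor, duplications double it in place, inversions reverse-complement it;
translocated segments stay in the donor but are excised from the
reference and appended as separate contigs, so boundary-spanning pairs
map interchromosomally, so the
reciprocal junctions of an insertion appear without simulating a second
derivative chromosome.

Instead of an external aligner, reads are projected through the exact
donor↔reference block map: a read inside one collinear block maps at its
lifted coordinate and strand; a read overhanging a junction by more than
m = 5 bp is emitted unmapped with its mapped mate. The margin mimics an
aligner's tolerance for sloppy ends, but conservatively: a soft-clipping
aligner keeps reads with much larger junction overhangs mapped, so the
idealized projection yields slightly *fewer* usable discordant fragments
per junction than a soft-clipping aligner such as bwa would leave
mapped — visible as a one-point sensitivity deficit for paired-end
deletion calling at 5× in some seeds —
while removing all mapping ambiguity, which pushes PPV toward 1. Mapping
quality is a constant 60 by default; an optional occurrence-check mode
assigns 0 to reads whose sequence occurs more than once in the reference
(meaningful only for repeat-bearing user genomes — a uniform random
reference has no repeats at read length, and the exact search scales
quadratically, so it is not the default). The generator does not model
indel sequencing errors, quality-score variation, repeat-structured
genomes, or heterozygosity: every planted event is homozygous and every
junction read is a perfect witness up to substitution errors.
Consequently, passing benchmarks here demonstrate the correctness and
calibration of the algorithm under clean mappings, and bound real-data
performance from above; they say nothing about alignment artifacts in
repeats, which only a real-aligner setup probes.

## Benchmark harness

Call sets are scored per SV type by greedy one-to-one matching against
the truth table: descending reciprocal overlap with a 0.8 floor for
intrachromosomal calls (a second call on the same truth counts as a false
positive); translocations count as recovered only when a merged call
places the insertion point and both segment boundaries within
`insert_max`. Sensitivity is TP/(TP+FN), PPV is TP/(TP+FP). Each grid
cell is simulated in five replicates at seeds `base..base+4` (the same
seeds across cells, so coverage columns differ only in coverage) and the
median over replicates is reported, separately for the paired-end-only
call set ("PE") and the precise split-read-refined calls ("SR"). The
default benchmark runs at half the full design's scale — 5 Mbp and 50
events per type (25 translocations) instead of 10 Mbp and 100 — which keeps a full cell under two minutes
on one CPU while leaving ~50-event denominators, granular enough for the
reported medians.

## Expected noise and known limitations

- ~0.13% of ordinary fragments exceed the 3·SD insert cutoff, producing
  low-support spurious deletion-signature clusters (~30 per 5 Mbp at 15×).
  They cap paired-end deletion PPV around 0.6–0.7 — the level aligner-based
  benchmarks of this design also report — and are the reason split-read
  confirmation exists: such clusters have no junction reads and their
  ~250 bp pseudo-sizes fail the 10% consistency check, so refined call
  sets are clean of them.
- Same-type events sharing an endpoint collapse into a single call
  (single clique per component).
- Non-template junction insertions of at least half the read length are
  undetectable by construction of the two-diagonal coverage rule.
- The gapless consensus tolerates substitution errors only; reads with
  indel sequencing errors near the junction are typically rejected by the
  k-mer filters rather than misaligned (a realignment-based gapped
  consensus is a possible extension, not implemented).
- Coordinates are 0-based half-open internally; all text output is
  1-based. All randomness flows from explicit integer seeds; equal seeds
  give byte-identical call sets.
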