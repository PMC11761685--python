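# Methods

This note documents the models, conventions and defaults behind `aavswap`,
what the simulator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## The assay and its data model

Each library member is a dual-barcoded AAV cargo: a 15-nt BC1 and a 16-nt
BC2, each flanked by constant *signposts* (left BC1 upstream 10 nt, left
BC1 downstream = the 33-nt Nextera R1 handle, right BC2 upstream 20 nt,
right BC2 downstream 20 nt), with a library-specific insert plus a 10-nt
internal index between the barcode blocks and filler sequence padding the
construct to a fixed ITR-to-ITR footprint (default 2,300 nt). A *chimera*
(barcode swap) is a packaged genome whose BC1 and BC2 trace to different
parental molecules; it is observable as a discordant pair in a single long
read, given a dictionary of true pairs.

The assembled map between the insert and the right signpost is not fully
constrained by the assay chemistry; the simulator places the partial
Nextera R2 handle (34 nt, standard mosaic-end adapter), then the index,
then an optional spacer (default 0 nt) immediately left of the right
BC2-upstream signpost, and the parser extracts features at the same
signpost-relative offsets, so the convention cancels between simulation
and parsing and is configurable for real designs
(`LibraryDesign.index_spacer_nt`, `r2_handle`).

## Dictionary construction

Filters run per side and then jointly, in this order (all radii
Levenshtein, all comparisons after uppercase normalization, N never
matches):

1. pile-up of exact (BC1, BC2) read counts; wrong-length barcodes are
   rejected and counted;
2. per-barcode totals over pairs with ≥ `pileup_min` (3) reads; abundance
   classes: low ≤ 5 reads (treated as sequencing/PCR errors and excluded
   outright — never error-corrected toward mid/high), high ≥ `high_cutoff`,
   mid otherwise. The mid/high boundary is dataset-dependent (the
   representation histogram is trimodal); `high_cutoff` is required
   configuration and `propose_high_cutoff` suggests the log10-histogram
   valley;
3. optional dominant-artifact removal: the dominant BC2 (given or argmax)
   plus every barcode within radius 2. `neighborhood_saturation` checks
   that the space is unsaturated at this tolerance;
4. artifact filters: ≥ 10 consecutive Gs, or the side's post-barcode
   truncation signature (`ATTAAAC` for BC1, `TAGCGCG` for BC2) as a
   substring;
5. mid-count pruning against the *pre-correction* high set (radius 2) —
   removing likely sequencing errors off abundant clones;
6. high-count error correction on the Levenshtein-≤2 graph: per connected
   component keep the argmax count; discard whole components when
   max/min < 10 or when the argmax is tied (conservative tie-break,
   mirroring the ambiguous-cluster rule);
7. unique-pairing filter: pairs with ≥ 2 reads, both barcodes in their
   valid sets, and strictly > 99 % of each barcode's reads concentrated on
   the pair, on both sides.

The uniqueness denominator counts a barcode's reads over all pairs above a
fixed floor of 2 reads. Keeping that floor independent of the retention
floor `min_pair_reads` makes retention monotone in both `uniqueness` and
`min_pair_reads` (with a shared floor, raising `min_pair_reads` can remove
competitors from the denominator and *promote* a borderline pair, which is
the wrong direction for a stringency knob).

Provenance counts are recorded at every step and are non-increasing along
the pair-filter chain.

## Long-read parsing

**Signpost search.** Each signpost is searched on both strands with an
infix edit-distance alignment (edlib), capped at
⌊(1 − min_identity) · L⌋ edits; identity is defined as (L − edits)/L, a
conservative proxy for the fraction of matching bases, thresholded at
0.75. This anchored search behaves like a local aligner for short fixed
queries at this threshold (2 substitutions in a 20-mer → 0.90, kept;
6 → 0.70, dropped) while being fast enough to parse hundreds of thousands
of reads per minute on one core. When the best edit distance is achieved
at two or more non-overlapping locations, or tied across strands, the
signpost is ambiguous and the read is rejected rather than resolved
silently.

**Layout.** A read passes when all four signposts have unambiguous best
hits on one strand in construct order (BC1 block before BC2 block on `+`,
reversed on `-`). Minus-strand reads are reverse-complemented (and hit
coordinates mirrored) before extraction, so every reported feature is
strand-invariant; this is tested as an invariant (reverse-complementing
all input reads changes no downstream tally).

**Features.** Coordinates are 0-based half-open on the forward strand.
BC1 is the interval between the left signposts, BC2 between the right
ones; the index window and insert end are placed at fixed signpost-relative
offsets (see above). `bc_to_bc_len` runs from the first BC1 base to the
last BC2 base; the full-length window is derived *and applied* under the
same convention, so the endpoint choice cancels in classification.

**Demultiplexing.** Levenshtein distance to all configured indices; a read
is unambiguous iff the best distance is ≤ 1 and the runner-up at least
2 edits further. The seven default indices are mutually ≥ 3 apart, so
the rule is unambiguous on exact indices.

**Dictionary matching.** Exact membership only — no error tolerance. A
read enters the swap denominator only if all of: layout pass, unambiguous
demultiplex, BC1 valid, BC2 valid, full BC-to-BC length. Reads failing any
filter carry an explicit rejection reason, and the reason breakdown sums
to the input count (a tested invariant).

**Length windows.** Full BC-to-BC: the 1 %–99 % empirical window
(nearest-rank quantiles, declared in output metadata) of zero-swap control
read lengths. Full ITR-to-ITR: fixed per-library windows (closed
intervals), e.g. 2,250–2,750 nt for standard AAV-packaged samples and
500–750 / 1,100–1,400 nt for the short/mid components of a multi-sized
library.

**Dimers.** Reads of roughly twice the expected length whose near-palindromic
hairpin (`GCGGACCGAGCGGCCGC`, ≤ 2 edits, either orientation) sits near the
midpoint with reverse-complement-similar flanks are split at the hairpin
and parsed from their forward pass, tallied separately so dimer vs
non-dimer comparisons are possible.

## Swap statistics

The resampling unit is the read (a Bernoulli outcome), with replacement,
independently within each sample — the standard nonparametric bootstrap
matching per-sample error bars; in the two-outcome representation this is
a binomial draw, which is how it is implemented (and how the exhaustive
enumeration oracle validates it). Intervals are 20th–80th percentile by
default. The one-sided bootstrap FDR for "sample *a* swaps more than *b*"
is the fraction of 10^5 paired resamplings in which *a*'s concordant
fraction comes out *higher* than *b*'s; ties count at weight ½, which
centers fdr(a, a) at 0.5. Because strict vs weak tie handling matters at
small n, both brackets (`fdr_strict`, `fdr_weak`) are reported alongside.
Seeds and resample counts are embedded in every comparison object.

Fisher's exact test is implemented by hypergeometric enumeration; the
two-sided p-value sums all tables at fixed margins whose probability does
not exceed the observed table's (with a 1 + 1e-7 relative guard against
floating-point ties); a zero margin returns p = 1 with a warning. It is
tested against an independent implementation on all tables with total
≤ 12.

## Insert annotation

Segments are filtered at match fraction strictly > 0.65 (matching bases /
alignment length including gaps), best-per-(read, start) retained, then
de-duplicated: two segments overlapping by > 50 % in the read frame are
redundant and the better match fraction wins, greedily from the best
segment down (the empirical overlap distribution is near-bimodal at
0 %/100 %, so the greedy order and the overlap denominator — overlap /
shorter segment, declared in metadata — are immaterial in practice).
Reads with exactly two disjoint segments on the same *circular* reference,
one starting within 5 nt of the reference start and/or one ending within
5 nt of its end, are re-categorized as simple (junction-spanning); the fix
only ever converts composite to simple. Categories: 0 segments →
not_mapped, 1 → simple, ≥ 2 → composite.

The built-in reference aligner is a seed-free affine local alignment
(Biopython PairwiseAligner) applied best-first with recursion into
unaligned flanks. It uses stricter scoring (+2/−4/−6/−2) than the homology
calls and a 50-nt minimum segment span: with permissive scoring an affine
local alignment can extend across a chimeric junction by gap-hopping
through unrelated sequence, and random sequence produces short spurious
local hits above the 0.65 identity filter — both artifacts a production
mapper's chaining suppresses natively.

Homology calls use the +2/−2/−3/−1 local scheme (configurable; raw scores
are always exported so score-cutoff analyses are reproducible under any
scheme). The null threshold is the maximum score over `n_null` = 1,000
draws of one sampled insert versus a single uniform permutation
("1-shuffle") of another sampled insert, giving an empirical FDR of about
1/1,000; the threshold grows with insert length (Gumbel-like), so it is
computed per library. The analytic cross-check for tagmented libraries is
E[shared-origin pairs] = f² · (L_insert / L_plasmid), where f is the
fraction of inserts deriving from the plasmid.

## The simulator

`generate_barcode_truth` rejection-samples barcodes with a minimum
pairwise Levenshtein distance per side, using a pigeonhole partition index
(exact, no false negatives) so the ~20k-pair bottlenecked-library scale is
reachable in seconds. Candidates containing the dictionary artifact
signatures (10+ Gs, truncation signatures) are rejected: such barcodes are
removed by the dictionary filters *by design*, so they cannot be members
of a validated dictionary and simulating them as truth would make the
truth unrecoverable by construction.

`simulate_association_reads` draws per-pair depths Poisson(depth × clone
weight), with a configurable jackpotted subpopulation (default fold
×1,000), an optional dominant artifact BC2 capturing 2.5 % of reads by
default, and per-base substitution errors.

`simulate_packaged_reads` emits full-layout cargoes with:

* **label_swap** — with probability `swap_rate` the BC2 is replaced by a
  uniformly chosen other pair's BC2. Exact per-read rate control; used for
  parameter-recovery tests.
* **template_switch** — a mechanistic *model* (not an observed mechanism):
  a partner pair is drawn and a crossover occurs within the tract shared
  by the two templates with per-base probability `swap_rate`, i.e. with
  probability 1 − (1 − p)^L where L is the whole insert plus the 67 nt of
  adapter handles for homologous libraries, and only the 67 nt of handles
  for non-homologous ones. The short constant index/signpost anchors are
  treated as assay scaffold, not crossover substrate. This makes the
  realized swap rate length- and homology-dependent by construction.

Off-products: truncated reads retain a U(0.2, 0.6) fraction of the insert
(fillers stay at their nominal lengths so the read is genuinely short);
composite reads splice a forward fragment to a reverse-complemented
fragment of the insert (two mappable segments); parental carryover reads
use the insert-free parental design with its own index. Dimers are
forward pass + hairpin + reverse complement. Strand is uniform; ONT-like
noise (independent per-base substitutions, insertions, deletions) is
applied last; truth labels always refer to the pre-noise template. The
acceptance runs use substitution 1 % with 0.5 % indels split evenly
between insertions and deletions. Identical config + seed gives
byte-identical FASTQ and truth tables.

Non-homologous member inserts are exact-length random sequences
(size-matched by construction); library assignment is round-robin across
the supplied designs.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: realistic ONT error profiles (homopolymer-aware,
quality-correlated), ITR secondary structure and snapback species, real
genomic insert composition (simulated non-homologous inserts share *zero*
homology beyond the adapters, unlike tagmented genomic DNA with plasmid
carryover), packaging-efficiency and size-selection biases, and the actual
(unknown) chimera-formation mechanism — `template_switch` reproduces the
direction and shape of length/homology dependence, not its true rates.

## Problem sizes and defaults

Test and acceptance runs use deliberately desk-scale conditions chosen to
keep every stage exercised end to end: dictionaries of 300–1,000 pairs at
depth 30, packaged libraries of 4,000–10,000 reads at the full 2,300-nt
ITR-to-ITR footprint, 20 seeds for recovery claims, 10^5 bootstrap
resamples, 1,000-draw homology nulls (reduced in unit tests). The swap
recovery criterion checks the pipeline estimate against the 99 % binomial
interval of the injected rate over qualifying reads; qualification is
independent of swap status under `label_swap`, so the estimate is unbiased
even though noise removes ~45 % of reads from the denominator via exact
barcode matching.

## Known limitations

* Signpost identity is edit-distance based, not alignment-score based; for
  badly degraded reads the two can diverge below the 0.75 threshold.
* The recursive built-in aligner is O(read × reference) per segment and
  meant for desk-scale references (tens of kb); use an external mapper and
  feed `AlignmentSegment`s directly for genome-scale work.
* `propose_high_cutoff` is a histogram heuristic; the mid/high boundary
  should be inspected on real data.
* The BC1 window discrepancy (a 16-cycle read window for a 15-nt barcode)
  is surfaced as a configurable extraction window, not resolved.
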