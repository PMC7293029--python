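# Methods

## Scope and model

lg4kit identifies long G4-capable regions (LG4s) by G-triplet density rather
than by minimal quadruplex motifs. The underlying model: a genomic interval
can adopt extended, composite G4 structure when it carries many GGG runs per
unit length, regardless of exact loop geometry — the situation at
immunoglobulin class-switch regions. The scanner therefore thresholds the
count of G-triplets inside a sliding window and reports maximal qualifying
intervals; motif-level analysis, loop pairing and genomic association are
downstream of that call.

All coordinates are 0-based half-open internally and in BED output;
human-readable reports print 1-based inclusive. Soft-masked (lowercase)
sequence is upper-cased and scanned — LG4s are repetitive and would
disappear under repeat masking. IUPAC ambiguity codes other than N are
coerced to N (with a warning) because triplet and loop logic is defined only
on concrete bases; runs and loops never span N.

## Scanner

Parameters (`ScanParams`):

| parameter | default | meaning |
|---|---|---|
| `window` | 1500 bp | sliding-window width, calibrated on the ~1.5 kb Sμ switch region |
| `threshold` | 121 | minimum triplets per window (Sμ carries ~120/1.5 kb) |
| `step` | 1 bp | window start spacing |
| `triplet_mode` | `floor3` | triplets credited per maximal run of length L |
| `min_density` | 1000·T/W ≈ 80.67/kb | post-refinement density floor |

Triplet counting inside runs longer than three is genuinely ambiguous;
`floor3` (⌊L/3⌋ non-overlapping triplets) credits long runs without
overlap inflation and is the default. `per-run` (one per run) and
`overlapping` (L−2) are provided because genome-wide totals depend on the
rule. A run contributes only to windows containing it entirely, computed
with a difference-array prefix sum whose equality with a naive per-window
recount is enforced by tests.

The GGG and CCC patterns are thresholded independently and combined as the
union of qualifying windows. Counts are never summed across patterns:
summing would fire on generic GC-rich sequence that cannot form G4 on
either strand. Overlapping or bookended qualifying windows merge into
maximal regions; regions of opposite patterns merge when they overlap by at
least one base and are labelled `both`.

Refinement clips each merged region to the first and last run (length ≥ 3
of the relevant base) it contains, recomputes the triplet count on the
refined span (for `both` regions, the richer pattern's count) and drops
loci below `min_density`. This matters near the threshold: a merged region
always includes sliding-window overhang beyond the dense core, and the
density floor removes calls whose refined span is not actually
triplet-dense. Sequences shorter than one window are evaluated as a single
window so unit fixtures behave sensibly. Degenerate regions with no
triplet-bearing run are dropped with a logged warning.

## Minimal G4 motifs

Motifs are four ordered G-runs of at least `min_g` = 3 bases with loops of
`loop_min` = 0 to `loop_max` = 36 nt and total span ≤ `max_len` = 45 nt —
filters that select for intramolecular quadruplexes. Runs are anchored at
maximal-run starts; a run longer than `min_g` contributes every prefix
length up to its full length, and candidates identical in all four run
intervals are reported once. Enumeration is exhaustive (tests compare it
against an independent brute-force oracle), so no scoring heuristic is
needed: density uses a deterministic greedy non-overlapping selection
(smallest start, tie smallest end) rather than a proprietary
representative-picking score. Densities sum motifs found on the given
strand and on its reverse complement, divided by interval length in kb;
zero-length flanks (locus at a chromosome end) are reported as missing
rather than zero.

## Loop extraction and kissing detection

Loops are the gaps between consecutive rich-base runs (length ≥ 3) inside a
locus; admitted loops are 5–39 nt (exclusive bounds 4 and 40) and N-free.
For `both`-strand loci the base with the higher triplet count defines the
runs. The unique-sequence set keeps first-occurrence coordinates.

Pairing replaces a heuristic local aligner with deterministic exhaustive
ungapped alignment — loops are at most 39 nt, so the full substring-pair
space is tiny, and exhaustive search removes seed/e-value nondeterminism.
Gapped alignments are excluded; reported lengths are literal base-pair
counts. An alignment of the segment of loop *a* against the reverse
complement of the segment of loop *b* qualifies at length ≥ 6 with all
positions Watson–Crick complementary for 6–9 bp and ≥ 90 % (no wobble,
floor semantics: length 10 needs ≥ 9 matches) beyond that. Among
qualifying alignments the ranking is length, then percent, then leftmost
offsets; one best alignment is reported per unordered pair of distinct
unique sequences. A pure optimization gates the search: any qualifying
alignment tolerates at most ⌊len/10⌋ mismatches and therefore contains an
exact run of ≥ 5 matches, so pairs sharing no 5-mer (between *a* and
revcomp(*b*)) are rejected without alignment; the gate length is recomputed
from the thresholds so nonstandard settings stay lossless.

Each unique sequence is additionally aligned against its own reverse
complement. Qualifying self-hits flag loops that are palindromic or carry
internal complementarity — the loops that make repeated instances of one
sequence pair with each other. Locus classification is `self` when more
than half of the pairing mass (self-hits plus distinct pairs) is self-type,
`neighboring` otherwise, `none` with no pairing; the majority threshold is
a parameter. Per-locus pair counts include self-hits so that a locus of
repeated palindromic loops is classified `self` rather than `none`. Cohort
summaries average over loci with at least one pairing, and the cohort mean
pair length is weighted by each locus's pair count. The counting unit —
unique-sequence pairs, one best alignment each — is one of several
defensible units (loop instances, all alignments); it is the package's
fixed choice and is documented here because cohort statistics depend on it.

`expected_random_spacing(k) = 4^k` is the expected gap between occurrences
of a fixed k-mer under uniform i.i.d. bases — the yardstick for how
surprising dense intra-locus complementarity is (4096 bp for k = 6). Real
loop composition is not uniform, so this is an order-of-magnitude argument,
not a p-value.

## Genomic association

Controls preserve the exact length multiset of the test loci; each control
is placed uniformly over valid start positions (chromosomes weighted by the
number of fitting starts) with rejection resampling against an exclusion
set and, when a genome is supplied, against N runs; sampling without a
genome is coordinate-only, a documented limitation. Placement is
deterministic given the seed; unsatisfiable lengths raise after a bounded
number of tries.

Distances are end-to-end gaps (0 when overlapping); overlap means ≥ 1 bp
shared. Gene context classifies a locus as known-gene within 5 kb, else
predicted-gene within 5 kb, else unassociated. Transcribed-strand calls
follow the convention that mRNA copies the sense strand: a G-rich locus on
the gene's own strand yields G-rich mRNA, on the opposite strand C-rich
mRNA; `both` loci are not applicable. Variant profiles bin point features
per 100 bp (locus plus 1–2000 bp flanks) or per kb (locus plus 1 kb bins to
3 kb, plus rest-of-transcript when a transcript is given); bins clip at
chromosome ends with effective spans as denominators, and bin counts are
asserted to conserve the features overlapping the profiled span on every
call. Enrichment reports observed counts, per-replicate control counts,
fold versus the control mean (undefined when the mean is zero), and a
two-tailed one-sample t of the control counts against the observation — the
package's choice where no test is canonical. Distance enrichment reports
mean distances and the control/locus ratio ("times closer"); loci on
chromosomes absent from a feature set are excluded from means, never
imputed. The t-test defaults to Welch (a pooled flag exists), chi-square
uses no continuity correction, and degenerate inputs (zero variance,
degenerate tables) return a flagged result with a missing p-value rather
than a number.

## Synthetic benchmarks

The generator emulates: G-triplet-dense repeat regions built from GGG+loop
units, background of configurable GC, planted reverse-complement loop
pairs, telomeric TTAGGG tracts, loop-size negative controls and Poisson
variant hotspots. Defaults: two 125 kb chromosomes at GC 0.45; eight
detectable regions of 1.5–3 kb spanning 85–120 triplets/kb; four 1.5 kb
sub-threshold decoys at 60–75/kb (at most 112 triplets per window, below
the 121 threshold by construction); three kissing regions with four planted
~8 bp pairs each (matching the reported mean pair length scale); two
150 bp telomeric tracts; variant rates 0.02/bp inside detectable regions
vs 0.002/bp outside (a 10× hotspot). One master seed expands into
per-component child seeds, so output is byte-identical given config + seed.

Two deliberate departures from pure i.i.d. background keep recovery tests
meaningful. First, background windows that meet the scan threshold by
chance are locally resampled, so background alone never produces a call.
Second, a window-width buffer flanking every planted span is scrubbed of
G/C triplets, which makes planted boundaries identifiable (refinement ends
at the planted runs) and detection deterministic: a window overlapping a
planted region sees only that region's triplets. Filler loops inside
planted regions are drawn from an A/C alphabet — two A/C strings can never
base-pair — so a region's only qualifying loop pairs are the planted ones
(pair sequences are redrawn on the rare collision, and the assembled region
is verified by re-extraction). What this does *not* emulate: real LG4
flanks are themselves G-rich, loop composition is biased rather than
uniform-random, and real variant density is not homogeneous Poisson.
Passing recovery tests therefore demonstrates algorithmic correctness on
controlled inputs, not calibration of genome-wide totals, which also depend
on the triplet-counting rule and on manual boundary conventions that are
not part of this package.

## Numerical and engineering choices

Rolling window counts use integer difference arrays (no floating point);
density comparisons against the floor use exact arithmetic on
`triplets / (length/1000)`. Greedy motif selection and alignment ranking
break ties deterministically (leftmost). Test fixtures and benchmarks are
generated programmatically; suite-wide problem sizes (125 kb chromosomes,
20-seed sweeps, 100–500-instance oracle panels) were chosen to exercise
every code path at comfortable desk scale. Known limitations: the scanner's
genome-wide totals depend on the triplet-counting rule inside long runs
(hence the `triplet_mode` switch); kissing statistics depend on the
unique-pair counting unit; control sampling without a genome cannot avoid
assembly gaps; and no thermodynamic model of kissing stability is included
— pairing is purely sequence-complementarity-based.
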