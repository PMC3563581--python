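# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerically delicate choices.

## The design being modelled

One outbred full-sib family: two wild-caught parents and 96 offspring,
genotyped by RAD sequencing at SbfI sites.  Each locus is a fixed 59-nt tag
with at most one SNP.  In an outbred cross, each marker belongs to a cross
type determined by the parental genotypes:

| cross type | parents  | offspring ratio | informative meiosis |
|-----------|----------|-----------------|---------------------|
| B3        | AB × AB  | 1 : 2 : 1       | both                |
| D1        | AB × hom | 1 : 1           | female only         |
| D2        | hom × AB | 1 : 1           | male only           |
| —         | AA × BB  | all AB          | neither             |

This is the pseudo-testcross structure: the female map is built from D1 +
B3 markers using the female recombination fraction r_f, the male map from
D2 + B3 using r_m.

## Synthetic families (simdata)

Transmission is simulated directly as a Markov chain over ordered markers:
on each chromosome, each parent's transmitted homolog starts uniformly and
switches between the two parental haplotypes with probability equal to the
configured per-sex inter-marker recombination fraction.  No crossover
process or interference model is assumed — the true rf between adjacent
markers is then exactly the configured value, which is what recovery tests
need.  Kosambi distances are used only on the estimation side.

Defaults and their rationale:

* **29 chromosomes, 40 clean markers each** — the karyotype of the target
  species (2n = 58) and a marker density comparable to a dense single-family
  RAD map.
* **inter-marker rf 0.025 (female) / 0.021 (male)** — ≈ 2.6 / 2.1 cM per
  interval, putting the simulated female genome near the ~3,000 cM expected
  from the salmonid genome size at ~1 cM/Mbp, with male recombination
  reduced relative to female as observed across salmonids.  Published map
  *totals* for such data run substantially longer than the underlying
  genome because call errors and missing data inflate map length; those
  totals are treated as observations, not as generator truth.
* **coverage ~ NB(mean 49, k = 49)** — mean matches the reported average
  aligned-read depth; k = mean gives variance ≈ 2 × mean, a mild
  overdispersion consistent with the broad reported depth range.
  `coverage_dispersion=None` makes depth deterministic (used by contract
  tests).
* **psv_fraction 0.45** — collapsed paralogs are simulated as two
  duplicated copies with a fixed difference emitted under one tag: every
  individual receives reads from both copies (double depth, ~50:50 allele
  counts) and is called heterozygous.  PSV loci are generated *in addition*
  to the clean markers — genome duplication creates extra apparent loci, it
  does not remove real ones — and interleaved among them.  The default
  makes PSVs ~45% of all loci, mirroring the roughly half of putative RAD
  SNPs that salmonid data loses to segregation distortion, most of it
  paralog-driven.
* **informativeness mix (0.50, 0.235, 0.235, 0.03)** for (B3, D1, D2,
  fixed-difference) — the proportions observed among mappable loci in a
  salmonid cross of this design (≈ 52% polymorphic in both parents, the
  remainder split between the parents, a small residue of fixed
  differences).
* **error_rate 0.005** — each read misreads the SNP-site allele with this
  probability (it then carries the *other* allele; novel alleles and indels
  are out of scope).
* **reads** — barcode (5 nt, generated with pairwise Hamming distance ≥ 2
  via a parity-check code) + `TGCAGG` + 59-nt tag + random filler to 80 nt
  (GAII layout); a configurable fraction of reads (default 2%) carries
  uniformly low qualities that fail the 80% rule.

What the generator does **not** emulate: position-dependent quality decay
along reads, indels, adapter read-through, chimeric tags, library-size
differences between individuals, true (non-paralog) segregation distortion,
and interference in crossover placement.  Passing tests therefore validate
the *pipeline logic* under the stated statistical structure, not robustness
to every artefact of real sequencers.

## Read processing

The 80% rule is implemented as **mean** per-base correctness ≥ 0.80, with
p = 1 − 10^(−Q/10): a raw "sum of probabilities" cannot be compared with a
percentage, so the mean is the only reading that makes the stated threshold
dimensionally sensible.  Trimming precedes filtering; demultiplexing is
exact-match on barcode and restriction-site remnant (no 1-mismatch rescue),
and tags containing non-ACGT symbols are discarded because the catalog and
the genotyper use exact sequence identity.

## Catalog

Unique-tag counting is exact.  The low-count filter (< 6 reads in a parent)
removes the sequencing-error peak; it is applied per parent, so a tag can
be trusted in one parent only.  Clustering is single-linkage at Hamming
distance ≤ 3 over the fixed-length tags — a portable replacement for
aligner-score cutoffs; degenerate chains are caught by the paralog rule
(more than two retained sequences overall, or in either parent, drops the
cluster).  Allele 1 is the lexicographically smaller sequence — the
reference-allele choice must be deterministic for reproducibility, and
nothing downstream depends on which allele is "reference".  Clusters with
no retained sequence in one parent get status `dropped_unshared`.

## Genotyping

Calls use the stated thresholds exactly: missing below 10 reads total; with
f = n2/(n1+n2), AB iff 0.28 ≤ f ≤ 0.80 (closed interval — "between
28%–80%" is read inclusively and the boundary behaviour is pinned by
tests), BB above, AA below.  Parents are called through the same rule.
Tags equal to neither allele are ignored, mirroring perfect-match
alignment.

## Marker QC

Cascade order is fixed: parent-missing removal → Mendelian
inheritance-error conversion to missing (marker removed if > 10% of its
scored offspring are impossible; the excess threshold is not prescribed
anywhere and is configurable) → χ² distortion test → missingness filter
(> 25%, strict, counting inheritance-converted missings).  The distortion
test uses observed classes only (missing excluded), no continuity
correction — with ~96 offspring the asymptotic χ² is adequate, and the
discreteness of Binomial(96, ½) puts the true size of the nominal 5% test
at 5.26%, which is what the operating-characteristic tests assert.
All-heterozygous PSV markers give χ² = n under the 1:2:1 test and are
removed with essentially unit power.

## Two-point linkage and maps

For a marker pair, a parent heterozygous at both loci transmits its two
parental haplotypes with probability (1−r)/2 each and recombinants r/2
each; a parent not doubly heterozygous contributes no linkage information.
The likelihood of the 3×3 joint genotype-class table is maximised over
(r_f, r_m) and phase; LOD is against r = 0.5.

* When only one parent is doubly heterozygous, offspring whose transmitted
  allele is readable at both loci (all offspring at D1/D2 loci; the
  homozygous classes at a B3 locus) give a binomial recombinant count and
  the ML is closed-form; the ambiguous AB class contributes a constant
  factor and drops out of the likelihood exactly.
* For AB×AB / AB×AB pairs the `two_point` API maximises the full mixture
  likelihood over the extended square (phase folded into r ∈ [0, 1] per
  parent) by exhaustive 0.001-grid scan.  **Map construction does not use
  these unconstrained estimates**: the joint (r_f, r_m) MLE is weakly
  identified — the anti-corner cells (AA,BB)/(BB,AA) have expectation
  n·r_f·r_m/2, already < 1 at moderate linkage, and when they are empty the
  MLE collapses onto the r_f = 0 (or r_m = 0) boundary ridge.  Those
  boundary estimates chain false "co-segregating" bins across whole
  chromosome arms.  The pairwise engine therefore estimates AB×AB pairs
  under the standard outcross constraint r_f = r_m = r, scanning the four
  phase combinations; this is also how the classical outcross mapping tools
  treat such pairs, at the cost of averaging the two sexes' rates on
  B3–B3 intervals.
* The all-pairs engine prunes with a vectorised screen before exact
  estimation: the closed-form subset LOD, plus (for AB×AB pairs, whose
  subset sees only ~¼ of offspring and none at all under opposite parental
  phases) a 2-df score statistic combining the centred-genotype-code
  cross-product with a homozygosity-association term.  The screen threshold
  (default LOD 1.5) is far below the grouping threshold of 6, so pruning
  cannot remove grouping-relevant edges.

Grouping follows the two-stage recipe: single-linkage bins at LOD ≥ 12 and
rf ≤ 0.01 with the least-missing member as representative (ties by locus
id), then connected components at LOD ≥ 6 (no rf gate at this stage).
Ordering minimises the sum of adjacent recombination fractions (SARF):
exhaustively for ≤ 7 markers, otherwise greedy nearest-neighbour seriation
from the tightest pair followed by an exhaustive sliding-window ripple
(window 4) accepting strict improvements until a full pass finds none.
SARF is used because the comparison criterion of the original ordering tool
is unstated and SARF is deterministic and cheap; orientation is
canonicalised by putting the end marker with the smaller id first.  Groups
with fewer than 4 markers are reported as fragments and excluded from map
totals; singletons are unplaced.  Adjacent fractions are clipped at 0.495
before the Kosambi transform (an adjacent estimate at the 0.5 boundary
would otherwise map to infinity).  Single-marker bridges (articulation
points whose removal splits a group into parts of ≥ 2 markers) are reported
for review, not auto-removed.

### Known limitation: exact chromosome recovery

At this design (96 meioses, ~28 QC-passed female-informative markers per
chromosome), LOD-6 grouping recovers exactly 29 groups per sex in most but
not all replicates: occasionally a run of single-parent-informative markers
attaches to its chromosome only through pairs whose exact LOD falls just
below 6 (the ambiguous-class loss halves the effective sample size of
D1–B3 pairs), splitting one group; and occasionally two chromosomes join
through chance block pseudolinkage with several cross edges marginally
above 6.  The original analysis of such data met the same phenomena and
resolved them by manual curation.  The modal group count across replicates
is robustly the chromosome number.

## Map comparison

Sex maps share only their B3 markers, so groups are compared on the span
between the most proximal and most distal *shared* markers; group pairing
is by majority vote of shared markers.  Fragment maps from additional
families merge when two or more markers overlap, anchored on the larger
fragment, with incompatible shared orders left unmerged and logged.
Cross-species tag matching is ungapped fixed-offset comparison on both
strands: full length with ≤ 1 mismatch for unmapped loci; overlap ≥ 56 nt
with ≤ 4 mismatches for mapped loci ("longer than 56 bp" is read as ≥ 56;
the stricter ≥ 57 reading is available through `min_overlap`).

## Numerical and reproducibility choices

* All randomness flows from one integer seed; lane generation uses
  per-lane child seeds so FASTQ output is byte-identical across runs and
  re-iterable lazily.
* Unique-row counting hashes rows to 64-bit keys and verifies the grouping
  against representatives, falling back to exact byte-wise unique on any
  collision.
* Zero cells in likelihood grids use log p = −10³⁰ sentinels so that
  structurally impossible cells exclude themselves without NaNs.
* Ties are broken deterministically everywhere (lexicographic locus ids,
  first-index argmax on fixed grids), making map tables invariant to input
  marker order.
* Default problem sizes in the tests (3-chromosome families for unit tests,
  ten full-design replicates for the recovery experiment) were chosen to
  keep the full suite and the acceptance script each around ten minutes on
  one CPU.
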