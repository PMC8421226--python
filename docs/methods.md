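# Methods

## Coordinates, sequences, formats

All intervals are 0-based half-open (BED convention) in memory; 1-based
coordinates appear only in labeled, human-readable report columns.
Genome sequence is uppercased on input, so soft-masked (lowercase)
regions are scanned like any other sequence — the motif count is defined
on sequence content, and no repeat-mask filtering is applied. Runs of
`N` never match any motif position, wildcards included: a wildcard means
"any real base". Alignments are read from MAF only (exactly two rows per
block, reference first); blocks recorded on the reference minus strand
are normalized by reverse-complementing both rows, which preserves the
alignment and flips the target strand annotation.

## Motif scanning

A degenerate IUPAC pattern is compiled into per-position allowed-base
sets, partitioned into fixed and wildcard (`n`) positions, and scanned
with an overlapping-window regular expression on the forward strand plus
a second pass with the reverse-complement pattern. A reverse-strand
match is reported at its forward-coordinate interval with strand `-`;
intervals matching on both strands are reported once. For the GR core
`GnACAnnnTGTnC` — which equals its own reverse complement — the
deduplication exactly halves the raw two-strand hit list, and strand is
not an identifiable property of an occurrence. Overlapping occurrences
are all reported; no greedy masking is applied.

## Homolog projection and the indel filter

Occurrences are projected through an interval-tree index over reference
block coordinates. A homolog is accepted (`ok`) only when a single block
covers the occurrence end-to-end and the covering columns contain no gap
in either row; the failure modes are explicit statuses (`unaligned`,
`partial`, `indel`), never errors. "No insertions or deletions" is
interpreted strictly — zero gap columns in *either* row across the
motif's columns — because downstream classification requires a
positionally comparable 13-mer. When several blocks fully cover an
occurrence (alignment redundancy), ties are broken deterministically by
lexicographic (target name, target start). The provided alignment is
taken as-is; no chain/net selection logic is applied.

## Variant classification and pooling

A homolog is compared to the consensus at the eight fixed positions
only; wildcard positions never constrain (divergence there is
invisible by design — the motif defines them as unconstrained).
Homologs with exactly one fixed-position mismatch at position 5 (or its
palindromic partner, position 9) are the informative class. Because the
motif is self-reverse-complementary, a position-9 variant with base X is
a position-5 variant with complement(X) on the other strand, so
position-9 variants are folded into the position-5 frame ("pooled").
The pooled base is never A (A is the consensus), and pooled G holds if
and only if the homolog retains a CG dinucleotide at positions 4–5 or
9–10 — the methylatable, deamination-capable ancestral state. Homologs
matching at positions 5 and 9 but mismatching elsewhere are `other`,
not partially counted. Pre-GBS candidates are deduplicated by the human
interval alone: support in several species collapses onto one record.

## Statistics

* **Spectrum uniformity.** Pooled C/G/T counts are tested against a
  uniform null (expected total/3 per base, df=2) with the standard
  goodness-of-fit statistic; stars follow the reporting thresholds
  `**` P<0.0001 and `*` 0.0001≤P<0.005. The uniform null is an
  interpretive choice — the three-category display this reproduces does
  not state its contrast — and is isolated in one function so it can be
  swapped. The direction of the G excess is reported separately.
* **Regulatory contrast.** Fisher's exact one-sided test on the 2×2
  table (regulatory / non-regulatory) × (pooled G / pooled C+T), with
  the alternative fixed as "regulatory enriched for G"; degenerate
  margins give p=1 by convention. No multiple-testing correction is
  applied across species (per-species thresholds are reported raw).
* **Overlap significance.** The upper hypergeometric tail
  P(X ≥ k | N, K, n) is evaluated through the survival function in log
  space, stable at genome-scale parameters (tails below 1e-50). The
  background population N is all scanned motif occurrences and K the
  regulatory ones; K is computed from the data, never assumed.

Both exact tests are validated in the test suite against independent
brute-force enumeration (all 2×2 tables with margins ≤15; integer
binomial-coefficient identities for the hypergeometric support).

## The genome-evolution simulator

The simulator exists to make every pipeline stage falsifiable at desk
scale; it is deliberately minimal rather than phylogenetically
realistic.

**Ancestor.** An i.i.d. background at a configurable GC content
(default 0.41, human-like) of length L (default 2 Mb), with
non-overlapping motif instances planted at uniform positions:
`n_cpg_sites` pre-GBS instances (`GnACGnnnTGTnC`) and `n_tpg_sites`
modern instances (`GnACAnnnTGTnC`), wildcards drawn uniformly. Defaults
are 500 and 1500: a 3:1 TpG:CpG ratio keeps the ancestral CpG state the
minority, in line with the strong TpG excess over CpG in vertebrate
genomes, while leaving enough CpG sites for stable desk-scale counts.

**Substitution model.** One generation of Bernoulli substitutions per
lineage, applied simultaneously from the pre-pass sequence (CpG context
is evaluated on the ancestor, so neighboring mutations within the pass
cannot interact). Every site substitutes to each different base with
probability μ/3 (default μ=0.02). At a CpG dinucleotide, the C→T
channel of the C — and, strand-symmetrically, the G→A channel of the G,
which is the C of the opposite strand — is elevated to
min(1, λ·μ/3): λ-fold the baseline C→T rate, matching the measured
10–50× acceleration of 5mC deamination over unmodified cytosine
(default λ=20, the midpoint). The two transversion channels of a CpG
cytosine stay at μ/3. Two consequences worth noting: λ=1 reduces
*exactly* to the background model, making it a clean null for the
recovery experiments; and λμ/3=1 (e.g. λ=50, μ=0.06) drives the
deamination channel to certainty, destroying essentially every CpG in
one generation. A single-generation model was chosen over a
continuous-time matrix because the downstream analysis is count-based,
not phylogenetic; this keeps the simulator exact and fast, at the cost
of not modeling back-mutation or rate heterogeneity. Known limitation:
per-site "intactness" varies slightly with the local context of planted
wildcards (extra CpG contexts at motif edges), which makes planted-site
outcome counts mildly overdispersed relative to a binomial.

**Indels.** Independent per-site events with probability δ (default
0.001), insertion or deletion with equal probability, geometric lengths
with mean 2. RNG streams are spawned per lineage and per operation, so
enabling indels does not perturb the substitution draws.

**Alignment.** The emitted MAF is the exact simulation record — the two
per-lineage edit records are composed column-wise through the ancestor
(columns deleted in both lineages are dropped; insertions carry a gap in
the sister row). No realignment ever happens, so projection through the
MAF is ground truth by construction.

**Regulatory track.** Each planted site is covered by a padded BED
interval (±25 bp) with probability ρ when it is deamination-derived
(planted CpG whose human-lineage copy became a consensus motif) and ρ0
otherwise (defaults 0.9 and 0.3), emulating selection preferentially
retaining newly functional sites. The truth table records, per planted
site, the ancestor and both descendant coordinates, the post-evolution
class per lineage, and the deamination-derived and regulatory flags.

**What the simulator does not emulate** — and hence what passing tests
do not show about real data: chromatin-informed motif placement,
context-dependent mutation beyond CpG, selection on sequence, more than
two taxa, realigner artifacts, and assembly or alignment error. Results
on real genomes additionally depend on the alignment track used
(net vs reciprocal-best), which is outside the pipeline's control.

## Desk-scale experiments

`recovery_experiment` sweeps the deamination multiplier λ over a grid
(the tests use {1, 5, 10, 20, 50}) at the default study conditions and
pools the variant spectra of three replicate genomes per λ before
computing the G fraction and the uniformity test — replication
stabilizes spectra of ~50–80 variants per genome without changing the
per-genome conditions. Expected behavior, which the acceptance tests
assert: at λ=1 the pooled spectrum is uniform (G count inside the
binomial 99% interval around 1/3, no chi-square star); the G fraction
rises monotonically in λ (up to 2.58-SE sampling slack); at λ=20 it
exceeds 0.5 with a `**` star. The λ=1 null is not exactly 1/3: planted
CpG sites whose position-5 G happens to transition contribute pooled-G
variants at rate μ/3 even without hypermutability, a small upward bias
(~0.03 at the default site ratio) that the interval comfortably absorbs.

`regulatory_power_experiment` measures the fraction of replicate
genomes in which the one-sided Fisher test rejects at α=0.05. At
ρ=0.9 vs ρ0=0.3 with 300 planted CpG sites (250 kb genomes, 900 TpG
sites), measured power is ≈0.55–0.63. This is a real ceiling, not a
tuning artifact: with μ=0.02 and λ=20 the probability that a planted
CpG site both converts in the human lineage and survives as a gapless
pooled-G homolog is ~0.05 — the conversion/destruction trade-off
x(1−x)³ (x the per-strand deamination probability) peaks near 0.057 —
so ~15 informative variants face a ρ0=0.3 background in each 2×2
table, and a design scan over the free parameters (TpG count, μ) tops
out near 0.63. The corresponding acceptance test asserts the ≥0.95
power its scenario calls for and is expected to fail; it documents the
sensitivity limit of the study conditions rather than a software
defect.

## Binding fits

The one-site hyperbola is fit by bounded least squares
(trust-region reflective; Kd seeded at the concentration nearest
half-saturation, f0/fmax at the signal extremes). Ligand depletion is
ignored by default — the probe is at 10 nM trace concentration, two
orders below the weakest Kd of interest — but a quadratic tight-binding
form with fixed probe concentration is available (`quadratic=True` /
`--quadratic`). Confidence intervals are nonparametric: titration
points are resampled with replacement (B=1000 by default, seeded) and
the 2.5/97.5 percentiles of the refitted Kd taken, widened to include
the point estimate if necessary; bootstrap replicates with flat or
near-degenerate resamples are discarded, and the fit is flagged
non-converged if fewer than a tenth survive or the optimizer sits on a
bound. The percentile bootstrap was chosen over asymptotic or
profile-likelihood intervals to avoid assumptions about the noise
model; its measured coverage at the assay design (12 log-spaced
concentrations 1 nM–50 µM, triplicate, 2% noise) is ≈0.90 for a
nominal 0.95, the familiar mild undercoverage of percentile intervals
at n=36. Degenerate (flat-signal) curves raise an error rather than
returning an unidentifiable Kd.

## Numerical choices and problem sizes

Simulation is vectorized over numpy uint8 code arrays (a 2 Mb genome
evolves in well under a second); the test suite and the acceptance
script run the pipeline at 2 Mb (λ grid), 250 kb × 100 replicates
(power), and 40–100 kb (unit tests) — sizes chosen so each experiment
gives stable statistics in seconds on one CPU. Exact-test oracles are
exhaustive where the space is small (tables with margins ≤15; the
hypergeometric support for N≤60) and randomized spot checks elsewhere.
All stochastic tests and experiments are seeded and fully reproducible.
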