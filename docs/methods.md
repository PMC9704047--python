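# Methods

This note documents the models, the synthetic study generator, the numeric
choices, and the limitations of `editdev`.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, strands and configuration

All internal coordinates are 0-based half-open; 1-based coordinates appear
only in VCF, pileup and site-table files (site ids are `chrom:pos1:strand`).
For a `forward` library the sequenced read maps to the transcript strand, so
a reverse-flag alignment comes from a minus-strand transcript; `reverse` is
the opposite.  For unstranded libraries a site's strand is taken from
overlapping gene annotation; positions covered by genes on both strands are
discarded and counted in the log — the protocol this package implements
considers strandedness "when appropriate" but gives no unstranded rule, so
the annotation fallback is this package's choice.

Every tunable threshold lives in one `FilterConfig` serialized as JSON.
Defaults are the published protocol values (de novo coverage ≥ 10 / edited
≥ 3 / ratio ≥ 1%; supervised ≥ 5 / ≥ 3; MAF mask 0.05; detection rate 0.70;
mean level 0.05; sample missingness 0.20; hyper-editing Phred 25/30, 5% of
read length, 60%/80% mismatch fractions with the 80% rule for reads ≤ 60 bp,
90% density, 20% read ends, 60% mono-nucleotide, 10% multimap margin; ±1 Mb
cis window; 1,000 permutations; 5% FDR).  Where the protocol names a rule but
not a number, the package fixes a documented default: read-end exclusion
6 bp, splice adjacency 4 bp, homopolymer run ≥ 5, imputation donors k = 5,
fold window 400 nt, minimum hairpin 3, seed length 20.

## Site calling

Pileups count quality-filtered bases (Phred ≥ 20, MAPQ ≥ 10) per
transcript-strand position, with read-end bases (first/last 6 bp) excluded
so that end-adjacent mismatch artifacts never enter the de novo path;
splice-adjacent positions (±4 bp of an annotated junction) are removed at
calling.  The two-caller consensus requirement is realized as the
intersection of ≥ 2 supplied call sets — in the bundled pipeline, the
internal caller run twice under perturbed base-quality cutoffs — since
reimplementing two published callers byte-for-byte is out of scope; any
external call table can be supplied instead.  Supervised (known-site) calls
bypass the consensus rule.  The removal filters (multi-allelic: ≥ 2 distinct
alt alleles with ≥ 2 reads each; homopolymer; blacklist; MAF-masked; sample
genomic call) are independent predicates, so the survivor set is identical
under any application order (property-tested).

Temporal detection groups follow the study's definitions: a site seen only
in prenatal samples, at a within-epoch detection rate ≥ 70%, is
prenatal-predominant (symmetrically postnatal); ≥ 70% across all samples is
common.  The source protocol states only "detected only in prenatal
samples", which is noise-fragile; the within-epoch 70% rule is this
package's tightening, and a flag switches the rate to global.

Missing cells in the common-site matrix are imputed by deterministic
k-donor matching: the k = 5 samples nearest to the recipient (mean squared
difference over co-observed sites) that have an observed value at the site
donate, and one donated value is drawn by seeded choice.  This keeps the
"borrow an observed value from a similar record" semantics of predictive
mean matching while being fully reproducible without iterative chained
equations; imputed values are always observed values of the same site.

### Attainable sensitivity

With the protocol's own thresholds, a site at level 0.05 under 20–30×
coverage yields ≥ 3 edited reads with probability only ~0.1–0.5 per sample
(binomial), so no faithful implementation can reach 95% per-sample recall at
the 5% level.  The suite therefore asserts the attainable site-level form:
sites with true level ≥ 10% at 30× are detected in at least one of six
samples ≥ 95% of the time (the union detection probability is ≈ 0.98), after
excluding sites the ledger removes by design (splice-adjacent, homopolymer).
The acceptance script reports both the per-sample recall over all ≥ 5% sites
and this union recall, as computed.

## Alu editing index

The index is depth-weighted — read-bases, not positions — matching "total
coverage of adenosines": every quality-passing base call at a reference-A
position inside an Alu interval adds to the denominator, and G calls (C on
minus-strand repeats) add to the numerator; masked common variants are
excluded and only reads with MAPQ ≥ 10 contribute.  The repeat family is a
parameter (Alu for primate, B1/B2 for mouse), and any substitution pair can
be indexed for noise diagnostics.  The index is exactly additive over read
chunks and monotone per added read-base (tested).

## Hyper-editing

The detector re-implements the transformed-alignment scheme with a built-in
desk-scale aligner: exact 20-mer seeds on the A→G-transformed reference
(both the sense transform and its complement T→C), ungapped extension with
≤ 10% mismatches in transformed space, no indels (the published scheme is
also ungapped), reference capped at 50 Mb.  Reads are tried in both
orientations under both transforms, because a sequencing read can represent
either strand of either transcript orientation; plus-strand edits are
recovered where the reference has A and the oriented read G, minus-strand
where T/C.  Among multiple placements the read is kept only when its edited
fraction of mismatches exceeds every alternative by ≥ 10%; a perfect
genomic read is strand-ambiguous by construction and is deliberately
discarded by this margin rule (it would fail the edit-count screen anyway).

Screen conventions: recovered edits count only at Phred ≥ 30; the
mismatch-fraction thresholds are strict inequalities (> 60%, > 80%), so a
4-of-5 read at ≤ 60 bp fails; the density rule fails reads whose edit span
exceeds 90% of the read length; "simple repeat" in the prescreen means ≥ 5
tandem copies of a 1–3 bp motif covering > 50% of the read (the source
protocol does not define it; configurable).  Cluster boundaries extend by
the floor of the mean inter-site spacing (single-site clusters by zero) and
overlapping same-strand clusters merge.  All twelve substitution types can
be screened by re-running the transform with the corresponding pair; on
A→G-only simulations the other types report zero sites (tested).

Gene-level differential hyper-editing regresses per-gene site counts
(missing = 0; genes kept when ≥ 1 site in ≥ 40% of samples) on the epoch
indicator with covariates; when gene lengths are supplied the across-gene
log-length trend is removed first.  BH adjustment is applied across genes.

## Temporal statistics

The headline contrast is the binary prenatal/postnatal indicator (a log-age
linear term is available).  Per-site inference is ordinary least squares
with a two-sided t test on the epoch coefficient — the moderated-variance
shrinkage of the original linear-model framework is deliberately replaced by
plain OLS, which is deterministic and dependency-free; the quantities being
scored here are planted-effect recovery, not shrinkage behavior.  Delta
editing is the difference of epoch means on the raw level scale.  Cohen's d
uses the pooled-SD form without small-sample correction.  Random-effects
pooling is DerSimonian–Laird: τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) with
fixed-effect weights w = 1/v, then inverse-variance weights 1/(v + τ²); the
implementation matches an independent reference to 10 decimals on a frozen
example.  BH adjustment is the step-up rule implemented directly and tested
for exact agreement with an independent implementation.  Mann–Whitney uses
the exact null distribution of U when there are no ties and nA·nB ≤ 400
(literal enumeration of all C(n, nA) assignments is infeasible at that size;
it is used only when ties are present and C(n, nA) ≤ 2·10⁵), otherwise the
tie-corrected normal approximation.  Cell-fraction estimation is NNLS
against a signature matrix with renormalization to sum one.

## Structure energetics

The folding engine is a stacking-weighted Nussinov recursion: the energy of
a structure is the sum of nearest-neighbor stack terms over adjacent pairs
(embedded Watson–Crick table, fixed −1.0 kcal/mol for wobble-containing
stacks; the exact values are configuration, not science), minimum hairpin
loop 3.  A full loop-based engine can be plugged through the same contract.
Because isolated pairs are energy-neutral under stacking-only energies, the
optimization objective is lexicographic — minimum energy, then maximum
paired bases, then a traceback that prefers pairing the smallest opening
index — packed into a single integer DP value (energy in centi-kcal × 1024
minus the pair count), which makes the optimum well-defined, deterministic,
and verifiable by exhaustive enumeration (exact agreement on random short
sequences is part of the acceptance surface).  Sequences longer than the
400 nt window are folded in tiles and concatenated; hyper-region windows
default to ±1,000 bp around the cluster center.

Duplex energies scan every ungapped antisense offset of the miRNA against
the window and sum stack terms over consecutively paired positions; strict
mode requires perfect Watson–Crick complementarity at miRNA positions 2–8.
Only the thermodynamic comparison of the published tool is modeled; its
alignment-score component is out of scope.  Gene tiers from the differential
hyper-editing p values are: Tier 3 < 10⁻¹⁰ ≤ Tier 2 < 10⁻⁵ ≤ Tier 1 < 0.05
≤ Tier 0, with Mann–Whitney comparisons of Tier 3 against each other tier.

## cis-edQTL mapping

Associations use covariate-residualized levels and dosages (period, sex,
ADAR1/ADAR2, five ancestry components by default; dosage 0/1/2 from GT with
per-variant mean imputation; within-partition MAF floor 0.05).  Site-level
permutation is direct — no beta-distribution approximation of the adaptive
scheme — with N = 1,000 and p = (1 + #{perm min p ≤ obs}) / (1 + N);
permutations compare the maximum absolute residual correlation, which is
monotone in the minimum nominal p at fixed degrees of freedom.  FDR is BH
over all site-variant pairs within each partition, following the source
protocol's wording, though pair-level BH is conservative; a lead-variant-only
mode is provided.  The five-category classifier applies rules in order
(constant → predominant → trending), and the trending categories additionally
require FDR ≤ 0.05 in at least one partition so that "did not fit earlier
categories" never promotes pure noise — a documented interpretation, since
the source states no significance floor for trending.  The prenatal
partition boundary is a parameter (the source reports both periods 1–7,
n = 116 and periods 1–6, n = 112); the default is periods 1–7.

## Synthetic study generator

The generator emulates the statistical structure of the real study:

* **Reference** — one contig (default 100 kb) with gene models (5'UTR, CDS
  exons, introns, 3'UTR on alternating strands) and ~300 bp Alu-like repeat
  copies (5% divergence, ~40% inverted) planted in introns and 3'UTRs, plus
  a small miRNA set.  The Alu-like and non-Alu consensus sequences are fixed
  synthetic sequences generated once from a frozen stream.
* **Cohort** — 12 developmental periods with geometric age boundaries from
  50 post-conception days to 20 years and birth between periods 7 and 8 (the
  period table is configurable because the source cites but does not reprint
  it); ages log-uniform within periods; neuronal fraction a rising logistic
  of log-age; ADAR2 rising and ADAR1 falling with log-age; defaults
  n = 116 prenatal / 60 postnatal.
* **Truth** — sites placed preferentially in 3'UTRs/introns/Alu; biased
  sites follow logistic level trajectories with midpoints near birth
  (postnatal-biased rising, prenatal-biased falling), nulls are flat;
  optional edQTL variants add an additive logit-scale shift restricted to
  their active epoch; hyper regions are flagged repeat intervals with a
  per-adenosine edit probability.  A matrix-level constructor
  (`planted_matrix_truth`) provides near-step trajectories with exact
  planted deltas for the statistical study conditions.
* **Genotypes** — Hardy–Weinberg draws at the stated MAF, written as VCF.
* **Reads** — per sample, uniform read starts at Poisson-equivalent
  coverage; each read carries G at a selective site with that sample's true
  level; hyper-region reads edit every transcript-strand adenosine
  independently at the region's probability and are emitted only into the
  unmapped FASTQ pool, mirroring the real pipeline's input; sequencing error
  is strand-symmetric and uniform across substitution types (the simplest
  null that still exercises A-to-G specificity); editing is independent
  across sites within a read except in hyper regions, matching the
  selective/hyper dichotomy.  The bundled study presets also plant a
  genome-wide Alu editing rate rising with log-age (1%→4%), which is what
  the Alu editing index reads out.

What the generator does **not** emulate: splicing-aware reads, PCR
duplicates, quality-score error models beyond uniform ε, haplotype linkage
between selective sites, expression-level variation between genes, and batch
structure.  Passing tests therefore demonstrate correctness of the
algorithms and calibration under these idealized conditions, not robustness
to alignment artifacts or library-preparation biases in real data.

## Problem sizes

The test suite and acceptance script run the study conditions at sizes
chosen to be informative on a single CPU: a 60 kb reference with 6 genes for
site calling and the AEI (72 Alu copies ≈ 5,000 Alu adenosines for the AEI
recovery condition; 40-sample rising cohort for the age correlation), a 1 Mb
reference with 10,000 clean and 500 planted reads for hyper-editing
specificity/sensitivity, 500 + 500 sites × 60 samples for differential
editing, and 250 sites × 176 samples × 1,000 permutations for the edQTL
conditions.  The full suite runs in roughly two minutes and the acceptance
script in about one.

## Known limitations

* The built-in aligners are exact-seed and ungapped; indels, splicing and
  genome-scale references are out of scope by design.
* The folding model omits loop entropies and pseudoknots; only relative
  MFE/double-strandedness comparisons are meaningful.
* Pair-level BH after permutation is conservative for edQTL discovery.
* The imputation scheme is single-draw donor matching, not multiple
  imputation; uncertainty from imputation is not propagated.
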