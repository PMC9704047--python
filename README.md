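# editdev

Analysis toolkit for **developmental A-to-I RNA editing**: detection of
selective editing sites from RNA-seq alignments, the Alu editing index,
hyper-editing detection from unaligned reads, prenatal/postnatal differential
statistics, miRNA-duplex and RNA-secondary-structure energetics, and
temporally partitioned cis-edQTL mapping — together with a synthetic study
generator that plants ground truth for every stage.

## Who this is for

Adenosine-to-inosine (A-to-I) editing, catalyzed by ADAR enzymes, is read by
sequencers as A→G mismatches and is massively enriched in primate Alu
repeats, whose inverted copies form the double-stranded substrate.  Editing
levels rise sharply across brain development, and individual sites can be
under genetic control (edQTLs) whose effects differ between prenatal and
postnatal life.  `editdev` implements the complete desk-scale analysis a
transcriptomics group needs to study this process — from base counts to
temporally classified edQTLs — with every numeric threshold collected in one
configuration object and every stage scoreable against planted truth.

## The methods at the core

**Selective site calling.**  Sites are called from strand-resolved pileups by
a consensus protocol: de novo candidates need coverage ≥ 10, edited reads
≥ 3, editing ratio ≥ 1% and support from ≥ 2 callers; supervised queries of a
known-site catalog need coverage ≥ 5 and edited reads ≥ 3.  Removal filters:
multi-allelic events, homopolymer/blacklisted positions, common variants
(MAF > 0.05), and positions with a non-reference genomic call in the matched
sample.  Surviving sites are grouped by temporal detection pattern
(prenatal-predominant / postnatal-predominant / common, with pairwise Jaccard
overlap), assembled into a sites × samples matrix (detection rate ≥ 70%,
mean level ≥ 5%, samples ≤ 20% missing) and imputed by deterministic
k-donor matching.

**Alu editing index (AEI).**  Per sample,

&nbsp;&nbsp;AEI = 100 · (A→G mismatch read-bases) / (read-bases at reference adenosines),

restricted to Alu intervals on their annotated strand, depth-weighted,
excluding masked variants and low-MAPQ reads.

**Hyper-editing.**  Densely edited reads fail ordinary alignment, so reads
are screened (mean Phred ≥ 25, composition, simple repeats), every A is
collapsed to G in read and reference, and reads are re-placed by an
exact-seed + ungapped-extension aligner in transformed space (both
orientations × both strands; multi-placements resolved by a ≥ 10% margin on
the A→G fraction of mismatches).  Recovered edits must be Phred ≥ 30, number
≥ 5% of the read length and exceed 60% of all mismatches (80% for reads
≤ 60 bp), with density, read-end and composition screens.  Per-read clusters
are extended by their mean inter-site spacing and merged; the per-sample
signal is 10⁶ · sites / uniquely mapped bases.

**Temporal statistics.**  Per site, OLS of editing level on a
prenatal/postnatal indicator plus covariates (sex, ancestry, optionally
ADAR1/ADAR2 and neuronal fraction), two-sided t tests, Benjamini–Hochberg
FDR.  Effect sizes are pooled-SD Cohen's d, pooled across datasets with a
DerSimonian–Laird random-effects model.  Cell fractions come from
non-negative least squares against a signature matrix; gene-set overlap from
Fisher's exact test.

**Structure energetics.**  A stacking-weighted Nussinov dynamic program
folds edited and unedited copies of the same window (nearest-neighbor stack
terms, G:U wobble allowed, minimum hairpin 3; lexicographic objective so
results are deterministic and an exhaustive oracle exists).  miRNA duplex
energies are the best ungapped antisense alignment under the same stack
table, with a strict seed mode (perfect Watson–Crick complementarity at
miRNA positions 2–8).

**cis-edQTL mapping.**  For every site, allele dosages of variants within
±1 Mb are regressed on the editing level with covariates; site-level
significance uses 1,000 permutations of the covariate-residualized levels,
p = (1 + #{perm min p ≤ observed}) / (1 + N).  Three partitions (all /
prenatal / postnatal) feed a five-category temporal classifier: constant,
prenatal-/postnatal-predominant, prenatal-/postnatal-trending.

## Worked example

```bash
editdev simulate --preset small --seed 7 --out demo
editdev run --study demo --seed 7
```

prints (abbreviated):

```
Differential RNA editing (prenatal vs postnatal)
================================================
sites tested        61
samples             18
covariates          sex, ancestry1, ancestry2
FDR threshold       0.05
postnatal biased    10
prenatal biased     6
unbiased            45
median |delta|      0.0417

AEI-age Spearman rho: 0.983

cis-edQTL mapping
================================================
all        n=18   pairs=366    FDR<=5%: 0
prenatal   n=10   pairs=366    FDR<=5%: 0
postnatal  n=8    pairs=366    FDR<=5%: 0
```

The generator planted 80 sites in a 60 kb Alu-bearing reference over an
18-sample cohort.  61 sites pass the matrix filters; 16 are called
temporally biased at 5% FDR (10 rising postnatally, 6 falling), matching the
planted 40% biased fraction at this sample size.  The Alu editing index
tracks age almost perfectly (ρ = 0.98) because the generator plants a
rising genome-wide Alu editing rate.  At n = 18 no edQTL survives
pair-level FDR — the planted lead variants carry the smallest nominal p, but
power at this preset is intentionally small; the `edqtl` preset (n = 176)
recovers > 95% of planted loci.  Full tables are written under
`demo/results/`.

As a library, the statistical stages follow the model/results idiom:

```python
from editdev import DifferentialEditingModel
res = DifferentialEditingModel(levels, cohort, ["sex", "ancestry1"]).fit()
print(res.summary())
res.table  # per-site delta, t, p, BH-adjusted p, direction
```

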