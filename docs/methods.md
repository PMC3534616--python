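# Methods

`poolcap` implements the analysis side of two complementary designs for
population-scale rare-variant discovery by hybridization capture:

* **pooled (anonymous) mode** — DNA from N individuals is combined without
  labels; variants surface as low allele fractions in the pool, and calling
  must separate a 1-in-2N allele (0.5% for N = 92) from sequencing error;
* **indexed mode** — each individual's fragments carry a 7 bp in-line index
  at the 3' end of read 1, so reads can be demultiplexed and genotyped per
  person, at the price of index-switching cross-contamination.

This note records the models, parameter choices, numerical decisions and
limitations; every empirical number quoted here is produced by the package's
own tests or by `scripts/acceptance.py`.

## Sequencing error model

Errors are modeled per (strand, cycle, template base → observed base), with
an optional second order that also conditions on the preceding reference
base (4 contexts).  Rates are estimated from aligned reads of a variant-free
control (a PhiX174-style spike-in, or a locus with no known variation) after
collapsing to unique (strand, start, sequence) records and discarding reads
with more than 5 substitutions.  Each cell is pseudocount-smoothed:

    rate = (mismatches + p) / (opportunities + 4p),   p = 1 by default

so no rate is exactly zero.  "Second order" here means conditioning on the
preceding *reference* base in reference coordinates; this is a documented,
overridable choice (strand-specific tensors already separate read
chemistry), and unseen contexts fall back to the context-marginal rate.

**Cycle exclusion.** The cumulative per-cycle error is the sum of the twelve
substitution-type rates (context-marginalized).  A cycle whose cumulative
rate exceeds 0.02% (0.0002, configurable; the CLI accepts `0.02%`) on either
strand is excluded from variant calling entirely — its base calls contribute
neither mismatches nor coverage.

**Control sizing.** Because of the pseudocount, the cumulative floor with
zero observed errors is `12p / opportunities-per-cell`.  For the floor to sit
comfortably under the 0.02% threshold, each (strand, cycle, base) cell needs
≳10⁵ opportunities — roughly half a million *unique* control reads per
strand.  Simulated controls therefore use references of several megabases so
slot occupancy stays low: when many identical reads stack on the same start
position, deduplication keeps one error-free copy but every error-bearing
copy, inflating the estimated rates.  Real control data escapes this because
quality strings and sheared ends diversify otherwise identical reads.

## Pooled variant calling

Reads are trimmed to a uniform cycle count (80 by default), compressed to
unique sequences, and piled up over target intervals (+101 bp flank) with
per-strand, per-cycle allele counts.  For a candidate alternate allele the
null hypothesis is that every read on a strand errs toward that allele
independently with its cycle-specific model rate; the alt-read count is then
Poisson-binomial, and the statistic is the exact upper tail P(X ≥ k),
computed by convolving per-cycle binomial pmfs.  The convolution is exact at
any desk-scale depth (the published pool statistic of the original SPLINTER
line of work is defined in prior literature and is not re-derived here; this
exact tail test is the package's documented stand-in, behind a seam —
`strand_pvalue` — where an alternative statistic could be substituted).

A variant is reported only when log₁₀p ≤ −1.3 on **both** strands
independently; a site with zero depth on either strand is uncallable and is
emitted only in the coverage output.  Tail probabilities below ~10⁻³²⁰
underflow double precision and are clamped to log₁₀p = −320, far past any
decision boundary.

**MAF estimation.** For a passing call with pooled alt fraction f and
expected model error rate ē (read-weighted over contributing cycles),
k = round(2N · max(f − ē, 0)) clamped to [1, 2N], and MAF = k/2N — every
reported pool MAF lies on the k/2N grid.  With 200-fold coverage per allele
the planted k is recovered exactly in ≳95% of sites; at 20-fold per allele
the binomial noise on f makes ±1-allele misassignments common even though
detection itself is essentially perfect.

**1 bp indels** use the same both-strand machinery with a single pooled
per-cycle indel rate (deletion and insertion events counted separately in
the control; the substitution model says nothing about indels).  Indels
longer than 1 bp are out of scope.

**2N for large pools.** The pool allele count is a user parameter.  For a
92-person pool the literal published setting of 200 alleles is the default
used when reproducing that design, although 92 diploids carry 184
chromosomes; the parameter is deliberately not auto-derived.

## Indexed-mode genotyping

The diploid genotyper is a deliberate minimal stand-in for the
mpileup/bcftools stack, with its model stated exactly so tests can be exact:
maximum likelihood among hom-ref / het / hom-alt under a symmetric binomial
read model (alt probability e, ½, 1−e; e = 0.005 by default), ties broken
toward fewer variant alleles, variant genotypes requiring ≥2 supporting
reads.  Two post-processing rules follow the standard pipeline:

* **20% reclassification** — a het whose reference (resp. variant) read
  fraction is below 20% becomes hom-variant (resp. hom-WT).  Idempotent.
* **depth cap** — sites above a depth ceiling (1000 by default; 99999 for
  the permissive pooled-exome setting) are flagged as filter failures,
  guarding against collapsed repeats.

In concordance runs the genotype is evaluated on the array's A/B allele
axis (the alternate allele is designated, and only ref/alt-matching reads
are informative); free-calling mode picks the most frequent non-reference
base instead.

## Concordance against array truth

Sensitivity and specificity are genotype-level:

    sensitivity = (het∧het + homvar∧homvar) / (array het + array homvar)
    specificity = (homWT∧homWT) / (array homWT)

so a het call at a true hom-variant site *counts against* sensitivity.
Position filters: cohort no-calls, sub-threshold coverage, ambiguous allele
designations and chip duplicates are dropped (pooled mode); indexed mode
additionally drops positions within 15 bp of an indel call cohort-wide and
within 15 bp of a SNV call for that individual only (a SNV at the compared
position itself is the comparison, not an exclusion).

**Coverage thresholds are per chromosome.** The stratification thresholds
{3, 5, 10, 15, 20} are fold-coverage per chromosome; a diploid site enters
the ≥c stratum at read depth ≥2c.  Pooled-mode "coverage per allele" is the
site depth divided by 2N, taken at the position itself.

Rarity bins are defined on cohort variant-allele counts: rare ≤9 alleles,
with dedicated bins at exactly 4 alleles (≈2% MAF in 184 alleles) and
exactly 1 allele (≈0.5%).  MAF concordance is the squared Pearson
correlation (least-squares R²) between pool and array MAFs over positions
polymorphic by either method, with array MAF denominators excluding no-call
alleles.  Empty strata report as undefined, never as zero.

## Index switching (misattribution) estimation

At array-validated positions with cohort MAF in [39%, 59%] and a full call
rate, the variant-read share among individuals homozygous wild type is
r_obs; at fully wild-type positions the same share is the background b
(sequencing error and alignment artifacts).  The staged estimate is

    seen  s = max(r_obs − b, 0)
    total   = 2s          (at 50% MAF half of all switches land on a
                           matching genotype and are invisible)
    jumping-adjusted = total − j   (j = 0.7% by default, applied on request)

The doubling is exactly unbiased when switched reads land on a 50%-MAF
background; the simulation recovery tests plant switching at 1/3/5% and the
estimator returns it within Monte-Carlo error.  Both the read-weighted
aggregate r_obs and the per-sample average are reported, since the two
aggregations of the same counts differ slightly in unbalanced data.  Samples
with failed genotyping or aberrant behaviour are removed via an explicit
exclusion list, not auto-detection.

## Capture metrics

On-target is the fraction of aligned, duplicate-removed bases inside target
intervals; on/near-target extends intervals by ±250 bp.  Fold enrichment is
the on-target base fraction divided by the target's share of the genome — a
base-fraction definition; tool-specific denominators (e.g. Picard's) differ,
so enrichment values are comparable within this package but not to other
tools' outputs.  The overall raw-on-target identity is
`aligned% × on-target% / 100`.  Coverage histograms report the percent of
target bases at or above {3, 5, 10, 15, 20}×; inter-sample uniformity is the
average pairwise R² of per-interval coverage *ranks* (intervals with zero
coverage in any sample excluded); Ti/Tv is transitions (A↔G, C↔T) over
transversions, undefined when transversions are absent.  Duplicate marking
is exact (strand, start, sequence) identity — optical-duplicate detection is
out of scope.

## Synthetic data: what it emulates, and what it does not

The read-level simulator (`simulate_cohort` / `simulate_reads`) plants
variants at *exact* pool allele counts (chromosomes chosen without
replacement), draws uniform fragment starts with length ~ N(280, 100),
appends the sample index to read 1's 3' end (a flag moves it 5'), applies
per-cycle substitution errors (index bases included), exact-copy PCR
duplicates, and index switching as whole-pair relabeling to a uniformly
random other sample.  Defaults mirror the emulated study design: 101 bp
paired reads, 7 bp indexes, 92 individuals, 13.4% duplication, 3.4%
switching, seed 1729.  Provenance (true sample, coordinates, duplicate and
switched flags) accompanies every read, and a truth SAM removes the need for
an external aligner.

For the large accuracy experiments a column-level generator draws per-site
read counts directly (Poisson depth, binomial allele sampling, uniform error
reassignment), skipping read assembly; this is statistically identical at
the pileup level and keeps the full experiments in seconds.  The read-level
path is exercised end to end at smaller scale.

Not emulated: hybridization thermodynamics and GC-dependent capture
efficiency (the GC/coverage summary consumes externally supplied per-bait
values), quality-score variation (fixed Q30 placeholders), alignment error,
optical duplicates, and jumping-PCR chimera formation as a mechanism (its
rate enters only as the subtraction allowance).  Passing tests therefore
demonstrate correctness of the *analysis* under the stated generative model,
not robustness to alignment artifacts or capture bias in real libraries.

## Study conditions used by `scripts/acceptance.py`

* Indexed sensitivity/specificity: 2,000 sites × 92 diploids at 4 cohort
  variant alleles each, 0.5% per-base error; mean 8× per chromosome scored
  at ≥5×/chromosome, and mean 30× scored at ≥20×/chromosome.  Specificity
  uses the ≥160,000 hom-WT cells of the shallow run.
* Pooled sensitivity: 1,000 sites, 2N = 10, allele counts cycling 1–5,
  20-fold per-allele coverage split evenly across strands, 0.2% per-cycle
  error calibrated from 300,000 separate control reads.  A uniform error
  profile has no aberrant cycles, so the cycle-exclusion step removes none —
  exclusion exists to remove cycle-specific artifacts relative to a
  platform baseline, which a flat profile does not have.
* Demultiplexing: 100,000 reads across 24 samples, distance-≥2 codes, 1%
  per-base index error, one mismatch allowed.

## Numerical and degenerate-input decisions

* Coordinates are 1-based inclusive internally and in all reports; BED I/O
  converts from/to 0-based half-open.
* Best-alt selection breaks count ties toward the alphabetically first
  allele; multi-allelic sites report the best alternate only.
* `N` bases in an observed index mismatch every code; equal-distance index
  ties go to UNASSIGNED (safety over yield).
* Zero-opportunity error-model cells are pure pseudocount and logged as a
  warning; zero-depth strands make a site uncallable in pooled mode and
  NO_CALL in the genotyper; empty concordance strata are undefined (None).
* All randomness flows from one `numpy` Generator per run, seeded from the
  configuration; identical configurations produce byte-identical outputs.

## Known limitations

* The exact published pool statistic is approximated (exactly computed
  Poisson-binomial tail, but a different statistic than the original
  large-deviation formulation).
* Unique-read compression distorts allele fractions when read-start slots
  saturate (small references at very high depth) — an intrinsic property of
  compression on low-diversity data; the caller's accuracy experiments use
  realistic occupancies.
* The genotyper ignores base and mapping qualities by design; real-data
  error structure (context-specific, quality-correlated) is richer than the
  simulator's uniform substitution process.
* Read 2 of a pair is truncated to read 1's genomic span in the combined
  truth alignment, costing 7 bp of mate-2 coverage in read-level
  simulations.
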