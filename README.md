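# poolcap

Analysis toolkit for population-scale rare-variant discovery by
hybridization capture, with or without per-sample DNA indexing.

Sequencing many individuals for rare variants poses two linked problems.
In an **anonymous pool** (no per-sample labels), a variant carried on one of
2N chromosomes appears as an allele fraction of 1/2N — 0.5% in a 92-person
pool — and must be separated from sequencing error of comparable magnitude.
In an **indexed multiplex**, short in-line barcodes assign each read to its
person, but indexes can switch between molecules during library
amplification, silently moving variants between individuals.  `poolcap`
implements the complete analysis stack for both designs, plus a synthetic
data generator so every stage is testable offline with known truth:

* **error model** — per-cycle, per-strand, per-substitution error rates
  calibrated from variant-free control reads, with pseudocount smoothing and
  exclusion of aberrant cycles whose cumulative error exceeds 0.02%;
* **pooled caller** — strand-aware rare-variant detection: the alternate
  allele count on each strand is tested against the exact Poisson-binomial
  upper tail P(X ≥ k) under cycle-specific error rates, a call requires
  log₁₀p ≤ −1.3 on *both* strands, and the minor allele frequency is
  reported on the pool grid k/2N after subtracting expected error;
* **demultiplexer** — validated 7 bp index sets with pairwise Hamming
  distance ≥2, assignment with one allowed mismatch (single errors are
  always corrected, never cross samples; ties go unassigned);
* **genotyper** — minimal diploid ML caller (binomial model) with the 20%
  allelic-fraction reclassification rule and depth-cap filter;
* **concordance** — genotype-level sensitivity/specificity against array
  truth, stratified by per-chromosome coverage and rarity bins, plus pooled
  MAF R² and 1 bp indel agreement;
* **contamination** — index-switching rate estimated from mid-frequency
  (39–59% MAF) validated positions: observed variant-read rate in
  homozygous wild-type individuals, minus the zero-variant background,
  doubled (half of switches are invisible), optionally discounting the
  jumping-PCR allowance;
* **capture metrics** — duplication, on/near-target fractions, fold
  enrichment, coverage histograms, interval-rank uniformity, Ti/Tv.

See `docs/methods.md` for the models and their assumptions.

## Worked example

Pooled calling on a simulated 10-chromosome pool (from
`examples/03_pooled_variant_calling.py` — four variants planted at allele
counts 1–4, ~22-fold coverage per chromosome, 0.2% per-cycle error):

```
12201 columns piled up, 7 SNVs pass on both strands

pos     ref>alt  log10p(f)  log10p(r)   k  MAF    truth
4000    A>G         -78.0      -86.0   1  0.10   k=1
8000    C>T        -265.3     -213.1   2  0.20   k=2
8670    C>T          -2.2       -2.1   1  0.10   none (false positive)
11860   C>T          -1.3       -1.3   1  0.10   none (false positive)
12000   G>A        -320.0     -320.0   3  0.30   k=3
12948   A>G          -2.1       -2.1   1  0.10   none (false positive)
16000   T>C        -320.0     -320.0   4  0.40   k=4
```

All four planted variants are recovered with the correct allele count k
(MAF = k/10 on the pool grid); the three false positives sit right at the
−1.3 cutoff — a per-site false-positive rate of ~2×10⁻⁴ at this error rate —
while true variants clear it by two orders of magnitude or more.

The staged index-switching arithmetic (from `examples/05_index_switching.py`):

```
observed rate r_obs    = 1.91%
background (0 alleles) = 0.20%
estimated total switching = 3.41%  (planted: 3.4%)
```

The other examples cover simulation + demultiplexing, error-model
calibration with cycle exclusion, stratified genotype concordance, and
capture metrics; each prints its results with a line on what they mean.

## Command line

A thin CLI wraps the library stages:

```bash
poolcap simulate --config sim.yaml --outdir run/
poolcap demux    --indexes run/indexes.tsv --r1 run/reads_R1.fastq --r2 run/reads_R2.fastq --outdir demux/
poolcap errmodel --control control.sam --ref control.fa --order 2 --threshold 0.02% -o model.tsv
poolcap poolcall --sam aln.sam --ref ref.fa --targets targets.bed --model model.tsv --alleles 200 --cutoff -1.3
poolcap genotype --sam s1.sam --ref ref.fa --targets targets.bed -o s1.geno.tsv
poolcap concord  --mode pooled --calls pool_calls.tsv --array array.tsv
poolcap contam   --reads reads.tsv --array array.tsv
poolcap metrics  --sam s1.sam --ref ref.fa --targets targets.bed
poolcap run      --config run.yaml      # full pooled or indexed pipeline
```

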