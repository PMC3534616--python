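"""Simulate an indexed capture run and demultiplex it by in-line index.

Builds a small 8-person cohort with two planted variants, writes the paired
FASTQ a sequencer would emit (7 bp sample index at the 3' end of read 1),
then splits the reads back out per sample allowing one index mismatch.
"""
import numpy as np

from poolcap import (
    SimConfig,
    Variant,
    demultiplex,
    simulate_cohort,
    simulate_reads,
    validate_index_set,
)

cfg = SimConfig(
    seed=7,
    reference_length=8000,
    n_individuals=8,
    read_length=101,
    per_cycle_error=0.005,      # 0.5% per base, also hits the index bases
    duplication_rate=0.10,
    switching_rate=0.02,
    mean_depth=20,
    variant_spec=[Variant(2000, "A", "G", 3), Variant(5000, "C", "T", 1)],
)
truth = simulate_cohort(cfg)
reads = simulate_reads(truth)
print(f"{reads.n_pairs} read pairs from {cfg.n_individuals} individuals "
      f"({reads.duplicate.mean():.1%} duplicates, {reads.switched.mean():.1%} index-switched)")

index_set = validate_index_set(reads.index_codes)
assignment, trimmed_r1, result = demultiplex(reads.r1, index_set)

print(f"identifiable: {result.fraction_identifiable:.2%} "
      f"(codes at pairwise Hamming distance >= {index_set.min_pairwise_hamming})")
correct = (assignment == reads.true_sample).mean()
print(f"reads returned to their true sample: {correct:.2%} — the shortfall is "
      "index switching plus uncorrectable index errors, not demux mistakes")
print(result.to_frame().to_string(index=False))
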