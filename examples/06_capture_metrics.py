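"""Capture-efficiency report for one simulated sample.

Duplicate fraction, on-target and on/near-target base percentages, fold
enrichment, the coverage histogram at the standard thresholds, and the Ti/Tv
ratio of a call set.
"""
import numpy as np

from poolcap import (
    SimConfig,
    Variant,
    compute_metrics,
    simulate_cohort,
    simulate_reads,
    titv_ratio,
)

cfg = SimConfig(
    seed=31, reference_length=30_000, n_individuals=1, read_length=101,
    per_cycle_error=0.001, duplication_rate=0.13, switching_rate=0.0,
    mean_depth=25, variant_spec=[Variant(10_000, "A", "G", 1)],
)
reads = simulate_reads(simulate_cohort(cfg))
targets = [(5_001, 7_000), (12_001, 15_000), (22_001, 23_000)]  # 6 kb of 30 kb

aligned = reads.truth
aligned.duplicate = np.concatenate([reads.duplicate, reads.duplicate])
m = compute_metrics(aligned, targets, genome_size=cfg.reference_length,
                    total_reads=int(aligned.n_reads / 0.85))  # pretend 85% aligned
print(m.to_frame().to_string(index=False))
print(
    f"\nproduct identity: {m.aligned_percent:.1f}% aligned x "
    f"{m.on_target_percent:.1f}% on-target = {m.overall_on_target_percent:.1f}% "
    "of raw data usable on target"
)

calls = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]
print(f"\nTi/Tv of a toy call set: {titv_ratio(calls):.2f} "
      "(transitions A<->G, C<->T over everything else)")
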