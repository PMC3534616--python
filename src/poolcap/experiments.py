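"""Self-contained simulation experiments at the package's study conditions.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage(s) and measures an accuracy quantity against the simulation truth.
They are what the acceptance script and the heavier tests run; the problem
sizes are the package's documented desk-scale study conditions (see
docs/methods.md).
"""
from __future__ import annotations

import numpy as np

from .concordance import sensitivity_specificity
from .demux import assign_indices, generate_index_codes, validate_index_set
from .error_model import build_error_model
from .individual_caller import NO_CALL, genotype_counts, reclassify_counts
from .pool_caller import PileupColumn, PoolCallerParams, call_pool_variants
from .sim import simulate_control_reads, simulate_genotype_observations
from .contamination import (
    background_rate,
    estimate_switching,
    observed_misattribution,
)


def indexed_genotype_experiment(
    seed: int,
    n_sites: int = 2000,
    n_individuals: int = 92,
    alleles_per_site: int = 4,
    mean_depth_per_chr: float = 8.0,
    coverage_threshold_per_chr: int = 5,
    base_error: float = 0.005,
    min_alt_reads: int = 2,
    caller_base_error: float = 0.005,
    reclassify_fraction: float = 0.20,
) -> dict:
    """Genotype-level sensitivity/specificity of the indexed-mode caller.

    Simulates a diploid cohort with every site planted at the requested pool
    allele count, genotypes each (site, individual) cell on the site's two-
    allele axis (binomial ML + allelic-fraction reclassification), and scores
    exact-genotype agreement over cells whose read depth reaches the
    per-chromosome coverage threshold (depth >= 2 x threshold for a diploid).
    """
    obs = simulate_genotype_observations(
        n_sites, n_individuals, alleles_per_site, mean_depth_per_chr, base_error, seed
    )
    gt = genotype_counts(obs["ref"], obs["alt"], min_alt_reads, caller_base_error)
    gt = reclassify_counts(gt, obs["ref"], obs["alt"], reclassify_fraction)
    deep = obs["depth"] >= 2 * coverage_threshold_per_chr
    truth = np.where(deep, obs["truth"], NO_CALL)
    res = sensitivity_specificity(truth, gt)
    res["n_scored"] = int(deep.sum())
    res["n_carrier_scored"] = int((deep & (obs["truth"] > 0)).sum())
    res["n_homref_scored"] = int((deep & (obs["truth"] == 0)).sum())
    return res


def pooled_calling_experiment(
    seed: int,
    n_sites: int = 1000,
    two_n: int = 10,
    allele_counts: tuple[int, ...] = (1, 2, 3, 4, 5),
    depth_per_allele: float = 20.0,
    per_cycle_error: float = 0.002,
    read_length: int = 80,
    control_reads: int = 300_000,
    control_ref_length: int = 200_000,
    cutoff: float = -1.3,
) -> dict:
    """Sensitivity of the pooled caller on a small anonymous pool.

    The error model is calibrated from separate variant-free control reads
    carrying the same uniform per-cycle error, then variant sites with pool
    allele counts cycling through ``allele_counts`` are sequenced to
    ``depth_per_allele x two_n`` total reads split evenly across strands.  A
    site counts as detected only when the call names the correct alternate
    allele; the MAF recovery rate (estimated k equals planted k) is also
    reported.  A uniform error profile has no aberrant cycles, so no cycles
    are excluded here.
    """
    rng = np.random.default_rng(seed)
    from .seq import random_sequence

    control_ref = random_sequence(control_ref_length, rng)
    control = simulate_control_reads(
        control_ref, per_cycle_error, control_reads,
        seed=int(rng.integers(0, 2**31 - 1)), read_length=read_length,
    )
    model = build_error_model(control, order=1)

    L = read_length
    truth_k = np.array([allele_counts[i % len(allele_counts)] for i in range(n_sites)])
    ref_base = rng.integers(0, 4, n_sites)
    alt_base = (ref_base + rng.integers(1, 4, n_sites)) % 4
    depth_total = int(round(depth_per_allele * two_n))
    n_per_strand = depth_total // 2

    counts = np.zeros((n_sites, 2, L, 6), dtype=np.int32)
    e = per_cycle_error
    for s in range(2):
        # reads x sites, vectorized over all sites at once
        cyc = rng.integers(1, L + 1, size=(n_sites, n_per_strand))
        is_alt = rng.random((n_sites, n_per_strand)) < (truth_k / two_n)[:, None]
        template = np.where(is_alt, alt_base[:, None], ref_base[:, None]).astype(np.uint8)
        err = rng.random((n_sites, n_per_strand)) < e
        shift = rng.integers(1, 4, size=(n_sites, n_per_strand), dtype=np.uint8)
        obs = np.where(err, (template + shift) % 4, template)
        site_idx = np.broadcast_to(np.arange(n_sites)[:, None], cyc.shape)
        flat = ((site_idx * 2 + s) * L + (cyc - 1)) * 6 + obs
        np.add.at(counts.reshape(-1), flat.ravel(), 1)

    columns = [
        PileupColumn("pool", i + 1, int(ref_base[i]), counts[i]) for i in range(n_sites)
    ]
    params = PoolCallerParams(cutoff=cutoff, two_n=two_n, trim_length=read_length)
    calls, _ = call_pool_variants(columns, model, params)
    by_pos = {c.pos: c for c in calls}
    detected = np.array(
        [
            (i + 1) in by_pos and by_pos[i + 1].alt == "ACGT"[alt_base[i]]
            for i in range(n_sites)
        ]
    )
    k_correct = np.array(
        [detected[i] and by_pos[i + 1].k == truth_k[i] for i in range(n_sites)]
    )
    return {
        "n_sites": n_sites,
        "n_called": len(calls),
        "sensitivity": 100.0 * detected.mean(),
        "maf_exact_fraction": 100.0 * k_correct[detected].mean() if detected.any() else None,
        "per_count_sensitivity": {
            int(k): 100.0 * detected[truth_k == k].mean() for k in sorted(set(truth_k))
        },
    }


def demux_identifiability_experiment(
    seed: int,
    n_reads: int = 100_000,
    n_samples: int = 24,
    index_length: int = 7,
    per_base_error: float = 0.01,
    max_mismatch: int = 1,
) -> dict:
    """Fraction of reads with an identifiable index under index-base errors."""
    rng = np.random.default_rng(seed)
    codes = generate_index_codes(n_samples, length=index_length, min_distance=2, rng=rng)
    index_set = validate_index_set(codes)
    truth = rng.integers(0, n_samples, n_reads)
    obs = index_set.matrix[truth].copy()
    err = rng.random(obs.shape) < per_base_error
    shift = rng.integers(1, 4, size=obs.shape, dtype=np.uint8)
    obs = np.where(err, (obs + shift) % 4, obs).astype(np.uint8)
    assigned = assign_indices(obs, index_set, max_mismatch)
    ok = assigned >= 0
    return {
        "n_reads": n_reads,
        "identifiable_percent": 100.0 * ok.mean(),
        "misassigned_percent": 100.0 * (ok & (assigned != truth)).mean(),
    }


def contamination_recovery_experiment(
    seed: int,
    switching_rate: float,
    n_midfreq_positions: int = 150,
    n_zero_positions: int = 80,
    n_samples: int = 94,
    mean_depth: float = 40.0,
    base_error: float = 0.002,
) -> dict:
    """Recover a planted index-switching rate from mid-frequency positions.

    Genotypes at mid-frequency positions are Hardy-Weinberg draws at allele
    frequency 0.5; every read is re-labelled to a random other sample with
    probability ``switching_rate``.  The staged estimator's doubled rate
    should recover the planted value (the doubling is exact at 50% MAF).
    """
    from .concordance import ArrayGenotypeTable
    import pandas as pd

    rng = np.random.default_rng(seed)
    P = n_midfreq_positions + n_zero_positions
    geno = np.zeros((P, n_samples), dtype=np.int8)
    # condition mid-frequency positions into the selector's 39-59% window
    for p in range(n_midfreq_positions):
        while True:
            g = rng.binomial(2, 0.5, n_samples).astype(np.int8)
            maf = g.sum() / (2 * n_samples)
            if 0.39 <= maf <= 0.59:
                geno[p] = g
                break
    table = ArrayGenotypeTable(
        positions=pd.DataFrame(
            {"ref_id": "ref1", "pos": np.arange(1, P + 1), "ref": "A", "alt": "C"}
        ),
        genotypes=geno,
        samples=[f"s{j}" for j in range(n_samples)],
    )

    depth = rng.poisson(mean_depth, size=(P, n_samples))
    n_switched = rng.binomial(depth, switching_rate)
    n_own = depth - n_switched
    p_var_own = geno / 2.0
    pop_maf = geno.sum(axis=1, keepdims=True) / (2.0 * n_samples)
    var_true = rng.binomial(n_own, p_var_own) + rng.binomial(
        n_switched, np.broadcast_to(pop_maf, depth.shape)
    )
    wt_true = depth - var_true
    e = base_error
    var_obs = rng.binomial(var_true, 1 - e) + rng.binomial(wt_true, e)
    wt_obs = depth - var_obs

    bins, r_obs, sample_avg = observed_misattribution(wt_obs, var_obs, table)
    b = background_rate(wt_obs, var_obs, table)
    est = estimate_switching(r_obs, b, jumping_percent=0.0)
    return {
        "true_percent": 100.0 * switching_rate,
        "observed_percent": r_obs,
        "sample_average_percent": sample_avg,
        "background_percent": b,
        "total_percent": est.total_percent,
        "bins": bins,
    }


def cycle_exclusion_experiment(
    seed: int,
    elevated_cycles: tuple[int, ...],
    read_length: int = 80,
    baseline_error: float = 5e-6,
    elevated_error: float = 3e-4,
    n_reads: int = 1_000_000,
    ref_length: int = 5_000_000,
    threshold: float = 0.0002,
) -> set[int]:
    """Plant elevated per-cycle error and return the model's excluded set.

    The control geometry keeps slot occupancy low (1M reads over a 5 Mb
    reference) so unique-read deduplication does not bias the rates, and
    gives every (strand, cycle, base) cell enough opportunities that the
    pseudocount floor sits well below the exclusion threshold.
    """
    rng = np.random.default_rng(seed)
    from .seq import random_sequence

    ref = random_sequence(ref_length, rng)
    control = simulate_control_reads(
        ref,
        baseline_error,
        n_reads,
        seed=int(rng.integers(0, 2**31 - 1)),
        read_length=read_length,
        elevated_cycles=[(c, elevated_error) for c in elevated_cycles],
    )
    model = build_error_model(control, order=1)
    return model.excluded_cycles(threshold)
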