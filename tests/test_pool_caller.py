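"""Pooled calling: exact strand test, both-strand rule, MAF grid, indels."""
from itertools import product

import numpy as np
import pytest

from poolcap import (
    PoolCallerParams,
    build_pileup,
    call_pool_indels_1bp,
    call_pool_variants,
    compress_reads,
    estimate_maf,
    strand_pvalue,
    trim_reads,
)
from poolcap.pool_caller import ALLELE_DEL, poisson_binomial_tail
from poolcap.reads import AlignedReadSet
from poolcap.seq import random_sequence
from tests.conftest import make_column, uniform_column


def enumeration_tail(probs: list[float], k: int) -> float:
    """Independent oracle: brute-force over all 2^n outcome vectors."""
    total = 0.0
    for bits in product([0, 1], repeat=len(probs)):
        if sum(bits) >= k:
            pr = 1.0
            for b, p in zip(bits, probs):
                pr *= p if b else 1 - p
            total += pr
    return total


class TestStrandPvalue:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n_groups = rng.integers(1, 5)
            trials = rng.integers(0, 4, n_groups)
            probs = rng.uniform(0.0005, 0.3, n_groups)
            flat = [p for n, p in zip(trials, probs) for _ in range(n)]
            for k in range(0, int(trials.sum()) + 2):
                mine = poisson_binomial_tail(trials, probs, k)
                oracle = enumeration_tail(flat, k)
                assert mine == pytest.approx(oracle, abs=1e-9)

    def test_zero_alt_reads_gives_log10p_zero(self, flat_model):
        col = uniform_column(0, 2, n_ref_fwd=20, n_alt_fwd=0, n_ref_rev=20, n_alt_rev=0)
        assert strand_pvalue(col, 0, 2, flat_model) == 0.0

    def test_strong_signal_clears_cutoff(self, flat_model):
        col = uniform_column(0, 2, n_ref_fwd=90, n_alt_fwd=10, n_ref_rev=90, n_alt_rev=10)
        assert strand_pvalue(col, 0, 2, flat_model) < -10 < -1.3

    def test_alt_equals_ref_rejected(self, flat_model):
        col = uniform_column(0, 2, 5, 1, 5, 1)
        with pytest.raises(ValueError, match="alt equals"):
            strand_pvalue(col, 0, 0, flat_model)

    def test_zero_depth_strand_rejected(self, flat_model):
        col = uniform_column(0, 2, 5, 1, 0, 0)
        with pytest.raises(ValueError, match="zero depth"):
            strand_pvalue(col, 1, 2, flat_model)

    def test_pvalue_uses_cycle_specific_rates(self):
        """The same alt count is less surprising at a noisier cycle."""
        from poolcap.error_model import ErrorModel

        m = ErrorModel(read_length=10, order=1)
        m.opp[:] = 10_000
        m.mism[:, 2, :, :] = 200  # cycle 3 is 200x noisier
        noisy = make_column(ref=0, fwd=[(3, 0, 18), (3, 2, 2)])
        quiet = make_column(ref=0, fwd=[(7, 0, 18), (7, 2, 2)])
        assert strand_pvalue(noisy, 0, 2, m) > strand_pvalue(quiet, 0, 2, m)


class TestCompressAndPileup:
    def test_compress_equals_set_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 4, size=(40, 12)).astype(np.uint8)
        dup = base[rng.integers(0, 40, 200)]
        uniq, counts = compress_reads(dup)
        assert counts.sum() == 200
        oracle = {row.tobytes() for row in dup}
        assert {row.tobytes() for row in uniq} == oracle
        assert len(uniq) == len(oracle)

    def test_all_distinct_reads_unchanged(self):
        rows = np.array([[0, 1, 2], [3, 2, 1], [1, 1, 1]], dtype=np.uint8)
        uniq, counts = compress_reads(rows)
        assert np.array_equal(uniq, rows)
        assert counts.tolist() == [1, 1, 1]

    def test_three_identical_reads_one_record(self):
        rows = np.tile(np.array([[0, 1, 2, 3]], dtype=np.uint8), (3, 1))
        uniq, counts = compress_reads(rows)
        assert uniq.shape == (1, 4)
        assert counts.tolist() == [3]

    def _toy_reads(self):
        ref = random_sequence(60, np.random.default_rng(1))
        # 6 reads of length 8: 3 forward at 10, 2 reverse at 12, 1 forward at 14
        seq = np.vstack(
            [ref[10:18], ref[10:18], ref[10:18], ref[12:20], ref[12:20], ref[14:22]]
        ).copy()
        seq[1, 5] = (seq[1, 5] + 1) % 4       # mismatch at ref pos 15, cycle 6 (fwd)
        seq[3, 3] = (seq[3, 3] + 2) % 4       # mismatch at ref pos 15, cycle 5 (rev)
        return AlignedReadSet(
            "r", ref, seq,
            start=np.array([10, 10, 10, 12, 12, 14]),
            strand=np.array([0, 0, 0, 1, 1, 0], dtype=np.uint8),
        )

    def test_manual_pileup_counts(self):
        reads = self._toy_reads()
        cols = build_pileup(reads, [(16, 16)], flank=0)
        assert len(cols) == 1
        col = cols[0]
        assert col.pos == 16
        # position 16 covered by reads 0,1,2 (fwd), 3,4 (rev), 5 (fwd)
        assert col.depth(0) == 4 and col.depth(1) == 2
        assert int(col.counts[0, :, (col.ref + 1) % 4].sum()) + int(
            col.counts[0, :, col.ref].sum()
        ) + int(col.counts[0, :, (col.ref + 2) % 4].sum()) + int(
            col.counts[0, :, (col.ref + 3) % 4].sum()
        ) == 4
        alt1 = (int(reads.ref[15]) + 1) % 4
        assert col.counts[0, 5, alt1] == 1      # fwd mismatch at cycle 6
        alt2 = (int(reads.ref[15]) + 2) % 4
        assert col.counts[1, 4, alt2] == 1      # rev read at 12: offset 3 -> cycle 8-3=5

    def test_excluded_cycle_contributes_nothing(self):
        reads = self._toy_reads()
        cols = build_pileup(reads, [(16, 16)], flank=0, excluded_cycles={6})
        col = cols[0]
        alt1 = (int(reads.ref[15]) + 1) % 4
        assert col.counts[0, 5, alt1] == 0
        # all three start-10 forward reads hit this position at cycle 6 and
        # are masked wholesale; only the start-14 read (cycle 2) remains
        assert col.depth(0) == 1

    def test_target_restriction_with_flank(self):
        reads = self._toy_reads()
        cols = build_pileup(reads, [(16, 16)], flank=2)
        assert [c.pos for c in cols] == [14, 15, 16, 17, 18]

    def test_trim_reads_by_cycle(self):
        reads = self._toy_reads()
        t = trim_reads(reads, 5)
        assert t.read_length == 5
        # forward reads keep their first 5 offsets
        assert np.array_equal(t.seq[0], reads.seq[0, :5])
        assert t.start[0] == reads.start[0]
        # reverse reads keep cycles 1-5, i.e. the last 5 reference offsets
        assert np.array_equal(t.seq[3], reads.seq[3, 3:])
        assert t.start[3] == reads.start[3] + 3


class TestCalling:
    def test_alt_on_one_strand_only_is_no_call(self, flat_model):
        col = uniform_column(0, 2, n_ref_fwd=90, n_alt_fwd=10, n_ref_rev=100, n_alt_rev=0)
        calls, _ = call_pool_variants([col], flat_model, PoolCallerParams(two_n=10))
        assert calls == []

    def test_zero_depth_strand_is_no_call_but_covered(self, flat_model):
        col = uniform_column(0, 2, n_ref_fwd=90, n_alt_fwd=10, n_ref_rev=0, n_alt_rev=0)
        calls, coverage = call_pool_variants([col], flat_model, PoolCallerParams(two_n=10))
        assert calls == []
        assert len(coverage) == 1 and coverage.depth_rev[0] == 0

    def test_both_strand_signal_called_with_correct_allele(self, flat_model):
        col = uniform_column(0, 3, n_ref_fwd=95, n_alt_fwd=11, n_ref_rev=88, n_alt_rev=9)
        calls, _ = call_pool_variants([col], flat_model, PoolCallerParams(two_n=10))
        assert len(calls) == 1
        assert calls[0].alt == "T" and calls[0].k == 1

    def test_removing_one_strand_always_uncalls(self, flat_model):
        rng = np.random.default_rng(8)
        params = PoolCallerParams(two_n=10)
        for _ in range(10):
            col = uniform_column(
                0, 1, n_ref_fwd=int(rng.integers(50, 150)), n_alt_fwd=int(rng.integers(5, 20)),
                n_ref_rev=int(rng.integers(50, 150)), n_alt_rev=int(rng.integers(5, 20)),
                rng=rng,
            )
            calls, _ = call_pool_variants([col], flat_model, params)
            if not calls:
                continue
            gutted = make_column(ref=0)
            gutted.counts[0] = col.counts[0]
            again, _ = call_pool_variants([gutted], flat_model, params)
            assert again == []

    def test_maf_grid_property(self, flat_model):
        rng = np.random.default_rng(12)
        params = PoolCallerParams(two_n=10)
        cols = [
            uniform_column(0, 2, 100, int(rng.integers(5, 60)), 100, int(rng.integers(5, 60)), rng=rng)
            for _ in range(20)
        ]
        calls, _ = call_pool_variants(cols, flat_model, params)
        assert calls
        for c in calls:
            assert (c.maf * params.two_n) == pytest.approx(round(c.maf * params.two_n))
            assert 1 <= c.k <= params.two_n


class TestEstimateMaf:
    def test_stated_arithmetic(self, flat_model):
        # alt fraction ~0.098 with tiny expected error lands on k=1 of 2N=10
        col = uniform_column(0, 2, n_ref_fwd=461, n_alt_fwd=50, n_ref_rev=460, n_alt_rev=49)
        k, maf = estimate_maf(col, 2, flat_model, two_n=10)
        assert (k, maf) == (1, pytest.approx(0.10))

    def test_half_fraction_is_k5(self, flat_model):
        col = uniform_column(0, 2, n_ref_fwd=100, n_alt_fwd=100, n_ref_rev=100, n_alt_rev=100)
        k, _ = estimate_maf(col, 2, flat_model, two_n=10)
        assert k == 5

    def test_error_correction_subtracts_expected_rate(self):
        from poolcap.error_model import ErrorModel

        m = ErrorModel(read_length=10, order=1)
        m.opp[:] = 99_996
        m.mism[:] = 4999  # every cell rate 0.05
        for b in range(4):
            m.mism[:, :, b, b] = 0
        col = uniform_column(0, 2, n_ref_fwd=170, n_alt_fwd=30, n_ref_rev=170, n_alt_rev=30)
        k, _ = estimate_maf(col, 2, m, two_n=10)
        # raw fraction 0.15 minus expected error 0.05 -> 0.10 -> k=1
        assert k == 1


class TestIndels:
    def test_no_observations_no_calls(self, flat_model):
        col = uniform_column(0, 2, 50, 0, 50, 0)
        assert call_pool_indels_1bp([col], flat_model, PoolCallerParams(two_n=10)) == []

    def test_one_strand_indel_is_no_call(self, flat_model):
        col = make_column(ref=0, fwd=[(2, 0, 90), (2, ALLELE_DEL, 10)], rev=[(2, 0, 100)])
        assert call_pool_indels_1bp([col], flat_model, PoolCallerParams(two_n=10)) == []

    def test_planted_deletion_detected(self, flat_model):
        col = make_column(
            ref=1,
            fwd=[(2, 1, 90), (5, ALLELE_DEL, 10)],
            rev=[(3, 1, 85), (7, ALLELE_DEL, 12)],
        )
        calls = call_pool_indels_1bp([col], flat_model, PoolCallerParams(two_n=10))
        assert len(calls) == 1
        assert calls[0].kind == "DEL1" and calls[0].k == 1

    def test_deletion_from_simulated_reads(self):
        """End-to-end: planted 1 bp deletion at MAF 10% called from a pool."""
        from poolcap import SimConfig, Variant, simulate_cohort, simulate_reads
        from poolcap.error_model import build_error_model
        from poolcap.sim import simulate_control_reads

        cfg = SimConfig(
            seed=31, reference_length=4000, n_individuals=5, read_length=47,
            per_cycle_error=0.002, duplication_rate=0.0, switching_rate=0.0,
            mean_depth=250, variant_spec=[Variant(2000, "A", "-", 1)],
        )
        t = simulate_cohort(cfg)
        r = simulate_reads(t)
        ctrl = simulate_control_reads(
            random_sequence(1_000_000, np.random.default_rng(5)), 0.002, 100_000,
            seed=6, read_length=40, indel_rate=0.001,
        )
        model = build_error_model(ctrl, order=1)
        pileup = build_pileup(trim_reads(r.truth, 40), [(1995, 2005)], flank=0)
        calls = call_pool_indels_1bp(pileup, model, PoolCallerParams(two_n=10))
        assert any(c.pos == 2000 and c.kind == "DEL1" for c in calls)


class TestMafRecovery:
    def test_exact_k_recovered_at_200x_per_allele(self):
        """Deep pools (200-fold per allele) pin the allele count exactly for
        >=95% of sites across k = 1..5."""
        from poolcap.experiments import pooled_calling_experiment

        res = pooled_calling_experiment(
            seed=23, n_sites=250, depth_per_allele=200.0,
            control_reads=150_000, control_ref_length=1_000_000,
        )
        assert res["sensitivity"] == 100.0
        assert res["maf_exact_fraction"] >= 95.0


class TestNullBehaviour:
    def test_false_positive_rate_below_1e3_on_null_pool(self):
        """Monte-Carlo null: hom-ref pool at 0.2% error, default cutoff."""
        from poolcap.experiments import pooled_calling_experiment

        res = pooled_calling_experiment(
            seed=19, n_sites=3000, allele_counts=(0,),
            control_reads=150_000, control_ref_length=1_000_000,
        )
        assert res["n_called"] / res["n_sites"] < 1e-3


class TestParams:
    def test_positive_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            PoolCallerParams(cutoff=0.5)

    def test_tiny_pool_rejected(self):
        with pytest.raises(ValueError, match="allele count"):
            PoolCallerParams(two_n=1)
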