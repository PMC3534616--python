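"""Error-model estimation: pseudocount smoothing, contexts, cycle exclusion."""
import numpy as np
import pytest

from poolcap import ErrorModel, build_error_model, simulate_control_reads
from poolcap.seq import random_sequence


@pytest.fixture(scope="module")
def clean_control():
    ref = random_sequence(100_000, np.random.default_rng(7))
    return simulate_control_reads(ref, 0.0, 30_000, seed=8, read_length=24)


@pytest.fixture(scope="module")
def noisy_model():
    """Order-2 model from a 0.1% uniform-error control with low slot occupancy."""
    ref = random_sequence(2_000_000, np.random.default_rng(3))
    ctrl = simulate_control_reads(ref, 0.001, 150_000, seed=4, read_length=36)
    return build_error_model(ctrl, order=2)


class TestEstimation:
    def test_zero_error_rates_are_pure_pseudocount_floor(self, clean_control):
        m = build_error_model(clean_control, order=1)
        assert m.mism.sum() == 0
        r = m.rates()
        # direct formula check on every off-diagonal cell
        for s in range(2):
            for c in range(m.read_length):
                for b in range(4):
                    for o in range(4):
                        if b == o:
                            continue
                        assert r[s, c, b, o] == pytest.approx(1.0 / (m.opp[s, c, b] + 4.0))

    def test_uniform_error_recovered_per_cell(self, noisy_model):
        """Each of the 3 observed bases per template sees ~e/3 of the errors."""
        m = noisy_model
        # raw (un-smoothed) estimator so the pseudocount floor drops out
        raw = m.mism / m.opp[..., None]
        cells = np.array([raw[s, c, b, o] for s in range(2) for c in range(m.read_length)
                          for b in range(4) for o in range(4) if b != o])
        target = 0.001 / 3
        assert cells.mean() == pytest.approx(target, rel=0.05)
        # spread across cells consistent with binomial sampling noise
        se = np.sqrt(target / m.opp.mean())
        assert np.percentile(np.abs(cells - cells.mean()), 99) < 4 * se

    def test_order2_marginalizes_to_order1(self, noisy_model):
        m = noisy_model
        # counts: summing contexts reproduces the marginal counts except at
        # cycle-1 positions that have no preceding base (start offset 0 is
        # excluded from the simulator, so every position has context here)
        assert np.array_equal(m.mism2.sum(axis=2), m.mism)
        assert np.array_equal(m.opp2.sum(axis=2), m.opp)

    def test_unseen_context_falls_back_to_marginal(self, noisy_model):
        m = noisy_model
        s, c = 0, 5
        ctx = 2
        saved_mm = m.mism2[s, c, ctx].copy()
        saved_opp = m.opp2[s, c, ctx].copy()
        m.mism2[s, c, ctx] = 0
        m.opp2[s, c, ctx] = 0
        try:
            got = m.error_rate(s, c + 1, 0, 1, context=ctx)
            marginal = m.error_rate(s, c + 1, 0, 1)
            assert got == marginal
        finally:
            m.mism2[s, c, ctx] = saved_mm
            m.opp2[s, c, ctx] = saved_opp

    def test_discards_reads_with_many_mismatches(self):
        ref = random_sequence(10_000, np.random.default_rng(5))
        ctrl = simulate_control_reads(ref, 0.0, 2_000, seed=6, read_length=30)
        # corrupt a handful of reads far beyond the 5-mismatch allowance
        ctrl.seq[:20, :10] = (ctrl.seq[:20, :10] + 1) % 4
        m = build_error_model(ctrl, order=1)
        assert m.mism.sum() == 0  # corrupted reads dropped entirely

    def test_empty_input_rejected(self, clean_control):
        with pytest.raises(ValueError, match="no control reads"):
            build_error_model(clean_control.subset(np.array([], dtype=int)))

    def test_monotonicity_in_mismatches(self, clean_control):
        m = build_error_model(clean_control, order=1)
        before = m.error_rate(0, 3, 0, 2)
        m.mism[0, 2, 0, 2] += 5
        after = m.error_rate(0, 3, 0, 2)
        assert after > before


class TestCumulativeAndExclusion:
    def test_cumulative_is_sum_of_twelve_cells(self, flat_model):
        cum = flat_model.cumulative_cycle_error()
        assert cum.shape == (2, 10)
        assert np.allclose(cum, 12 * 1e-3)

    def test_zero_error_cumulative_equals_floor(self, clean_control):
        m = build_error_model(clean_control, order=1)
        cum = m.cumulative_cycle_error()
        floor = (1.0 / (m.opp + 4.0) * 3).sum(axis=2)
        assert np.allclose(cum, floor)

    def test_threshold_one_excludes_nothing(self, flat_model):
        assert flat_model.excluded_cycles(1.0) == set()

    def test_no_cycle_above_threshold_empty_set(self, flat_model):
        assert flat_model.excluded_cycles(0.02) == set()

    def test_elevated_cycle_flagged(self):
        """An elevated cycle at 0.03% crosses the 0.02% cumulative threshold."""
        from poolcap.experiments import cycle_exclusion_experiment

        exc = cycle_exclusion_experiment(
            seed=2, elevated_cycles=(16,), read_length=20,
            n_reads=1_000_000, ref_length=5_000_000,
        )
        assert exc == {16}

    def test_invalid_threshold_rejected(self, flat_model):
        with pytest.raises(ValueError, match="positive"):
            flat_model.excluded_cycles(0.0)


class TestContract:
    def test_lookup_matches_set_cell(self, flat_model):
        assert flat_model.error_rate(0, 4, 1, 3) == pytest.approx(1e-3)

    def test_obs_equals_ref_rejected(self, flat_model):
        with pytest.raises(ValueError, match="equals the template"):
            flat_model.error_rate(0, 4, 1, 1)

    def test_excluded_cycle_lookup_rejected(self, flat_model):
        flat_model.excluded = {4}
        try:
            with pytest.raises(ValueError, match="excluded"):
                flat_model.error_rate(0, 4, 1, 3)
        finally:
            flat_model.excluded = set()


class TestSerialization:
    def test_roundtrip_identity(self, noisy_model, tmp_path):
        p = tmp_path / "model.tsv"
        noisy_model.to_tsv(str(p))
        back = ErrorModel.from_tsv(str(p))
        assert back.read_length == noisy_model.read_length
        assert back.order == noisy_model.order
        assert np.array_equal(back.mism, noisy_model.mism)
        assert np.array_equal(back.opp, noisy_model.opp)
        assert np.array_equal(back.mism2, noisy_model.mism2)
        assert np.array_equal(back.opp2, noisy_model.opp2)
        assert np.array_equal(back.indel_counts, noisy_model.indel_counts)
        assert np.allclose(back.rates(), noisy_model.rates())

    def test_rewrite_is_byte_stable(self, noisy_model, tmp_path):
        p1, p2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
        noisy_model.to_tsv(str(p1))
        ErrorModel.from_tsv(str(p1)).to_tsv(str(p2))
        assert p1.read_bytes() == p2.read_bytes()
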