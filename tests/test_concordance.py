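"""Array concordance: filters, accuracy formulas, MAF and indel agreement."""
import numpy as np
import pandas as pd
import pytest

from poolcap.concordance import (
    ArrayGenotypeTable,
    filter_positions_indexed,
    filter_positions_pooled,
    indel_concordance,
    pooled_maf_concordance,
    sensitivity_specificity,
    stratified_report,
)
from poolcap.individual_caller import HET, HOM_ALT, HOM_REF, NO_CALL


def make_table(genotypes: np.ndarray, pos=None) -> ArrayGenotypeTable:
    g = np.asarray(genotypes, dtype=np.int8)
    n_pos, n_samp = g.shape
    pos = pos if pos is not None else np.arange(1, n_pos + 1)
    return ArrayGenotypeTable(
        positions=pd.DataFrame({"ref_id": "ref1", "pos": pos, "ref": "A", "alt": "C"}),
        genotypes=g,
        samples=[f"s{j}" for j in range(n_samp)],
    )


class TestTable:
    def test_tsv_roundtrip(self, tmp_path):
        t = make_table([[0, 1, 2], [2, -1, 0]])
        p = tmp_path / "array.tsv"
        t.to_tsv(str(p))
        back = ArrayGenotypeTable.from_tsv(str(p))
        assert np.array_equal(back.genotypes, t.genotypes)
        assert back.samples == t.samples
        # byte-stable rewrite
        p2 = tmp_path / "array2.tsv"
        back.to_tsv(str(p2))
        assert p.read_bytes() == p2.read_bytes()

    def test_maf_excludes_no_call_alleles(self):
        t = make_table([[1, -1, 0, 2]])
        # variant alleles 3, called alleles 6 (one sample NC)
        assert t.variant_allele_counts()[0] == 3
        assert t.mafs()[0] == pytest.approx(0.5)


class TestPooledFilter:
    def test_toy_counts(self):
        g = np.zeros((10, 4), dtype=np.int8)
        g[2, 1] = NO_CALL                      # one position with a cohort no-call
        cov = np.full(10, 30.0)
        cov[7] = 10.0                          # one position under 20x per allele
        mask = filter_positions_pooled(make_table(g), cov)
        assert mask.sum() == 8
        assert not mask[2] and not mask[7]

    def test_all_clean_retained(self):
        g = np.zeros((5, 3), dtype=np.int8)
        assert filter_positions_pooled(make_table(g), np.full(5, 25.0)).all()

    def test_chip_duplicates_keep_first(self):
        g = np.zeros((4, 2), dtype=np.int8)
        t = make_table(g, pos=[10, 20, 20, 30])
        mask = filter_positions_pooled(t, np.full(4, 25.0))
        assert mask.tolist() == [True, True, False, True]

    def test_ambiguous_alleles_dropped(self):
        t = make_table(np.zeros((2, 2), dtype=np.int8))
        t.positions.loc[1, "alt"] = "A"  # alt equals ref -> ambiguous
        mask = filter_positions_pooled(t, np.full(2, 25.0))
        assert mask.tolist() == [True, False]

    def test_filter_order_invariance(self):
        rng = np.random.default_rng(2)
        g = rng.choice([0, 1, 2, -1], size=(30, 5), p=[0.7, 0.15, 0.1, 0.05]).astype(np.int8)
        cov = rng.uniform(0, 50, 30)
        t = make_table(g)
        mask = filter_positions_pooled(t, cov)
        # independent re-derivation applying predicates in a different order
        oracle = np.ones(30, dtype=bool)
        oracle &= ~t.positions.duplicated(["ref_id", "pos"]).to_numpy()
        oracle &= cov >= 20
        oracle &= (g >= 0).all(axis=1)
        assert np.array_equal(mask, oracle)


class TestIndexedFilter:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["sample", "ref_id", "pos", "kind"])

    def test_indel_excludes_cohort_wide(self):
        t = make_table(np.zeros((1, 3), dtype=np.int8), pos=[110])
        calls = self._calls([("s0", "ref1", 100, "DEL1")])
        assert not filter_positions_indexed(t, calls).any()

    def test_snv_excludes_one_sample_only(self):
        t = make_table(np.zeros((1, 3), dtype=np.int8), pos=[110])
        calls = self._calls([("s1", "ref1", 100, "SNV")])
        elig = filter_positions_indexed(t, calls)
        assert elig[0].tolist() == [True, False, True]

    def test_window_boundary_16bp_retained(self):
        t = make_table(np.zeros((1, 2), dtype=np.int8), pos=[116])
        calls = self._calls([("s0", "ref1", 100, "DEL1")])
        assert filter_positions_indexed(t, calls).all()

    def test_snv_at_the_position_itself_not_excluding(self):
        t = make_table(np.zeros((1, 2), dtype=np.int8), pos=[100])
        calls = self._calls([("s0", "ref1", 100, "SNV")])
        assert filter_positions_indexed(t, calls).all()


class TestAccuracyFormulas:
    def test_perfect_agreement(self):
        t = np.array([0, 0, 1, 1, 2])
        res = sensitivity_specificity(t, t.copy())
        assert res["sensitivity"] == 100.0 and res["specificity"] == 100.0

    def test_hand_counted_example(self):
        # 10 het truth: 9 called het, 1 called hom-alt (counts against sensitivity)
        # 100 hom-ref truth: 1 called het
        truth = np.array([HET] * 10 + [HOM_REF] * 100)
        called = np.array([HET] * 9 + [HOM_ALT] + [HET] + [HOM_REF] * 99)
        res = sensitivity_specificity(truth, called)
        assert res["sensitivity"] == pytest.approx(90.0)
        assert res["specificity"] == pytest.approx(99.0)

    def test_het_for_homalt_counts_against_sensitivity(self):
        truth = np.array([HOM_ALT, HOM_ALT])
        called = np.array([HET, HOM_ALT])
        assert sensitivity_specificity(truth, called)["sensitivity"] == pytest.approx(50.0)

    def test_empty_stratum_undefined_not_zero(self):
        res = sensitivity_specificity(np.array([HOM_REF]), np.array([HOM_REF]))
        assert res["sensitivity"] is None
        assert res["specificity"] == 100.0

    def test_random_tables_match_hand_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            truth = rng.choice([-1, 0, 1, 2], 200)
            called = rng.choice([-1, 0, 1, 2], 200)
            res = sensitivity_specificity(truth, called)
            v = truth != NO_CALL
            sens_num = np.sum((truth == called) & np.isin(truth, [HET, HOM_ALT]) & v)
            sens_den = np.sum(np.isin(truth, [HET, HOM_ALT]) & v)
            spec_num = np.sum((truth == HOM_REF) & (called == HOM_REF) & v)
            spec_den = np.sum((truth == HOM_REF) & v)
            if sens_den:
                assert res["sensitivity"] == pytest.approx(100 * sens_num / sens_den)
            if spec_den:
                assert res["specificity"] == pytest.approx(100 * spec_num / spec_den)


class TestStratification:
    def test_site_sets_nest_across_thresholds(self):
        rng = np.random.default_rng(13)
        depth = rng.poisson(25, size=(50, 8))
        deep20 = depth >= 40
        deep3 = depth >= 6
        assert (deep20 <= deep3).all()

    def test_report_shape_and_monotone_counts(self):
        rng = np.random.default_rng(14)
        n_pos, n_samp = 60, 6
        truth = rng.choice([0, 1, 2], size=(n_pos, n_samp), p=[0.8, 0.15, 0.05]).astype(np.int8)
        called = truth.copy()
        depth = rng.poisson(30, size=(n_pos, n_samp))
        counts = np.where(truth > 0, truth, 0).sum(axis=1)
        rep = stratified_report(truth, called, depth, counts)
        assert set(rep["coverage"]) == {3, 5, 10, 15, 20}
        all_rows = rep[rep["maf_bin"] == "all"].sort_values("coverage")
        hets = all_rows["het_sites"].to_numpy()
        assert (np.diff(hets) <= 0).all()  # higher threshold, fewer scored sites


class TestMafConcordance:
    def test_identical_vectors_r2_one(self):
        m = np.array([0.1, 0.2, 0.0, 0.4])
        res = pooled_maf_concordance(m, m.copy())
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["n_positions"] == 3

    def test_toy_vectors_match_least_squares_oracle(self):
        pool = np.array([0.10, 0.22, 0.31, 0.38, 0.52, 0.0])
        array = np.array([0.12, 0.20, 0.30, 0.41, 0.50, 0.0])
        res = pooled_maf_concordance(pool, array)
        sel = (pool > 0) | (array > 0)
        r_oracle = np.corrcoef(array[sel], pool[sel])[0, 1] ** 2
        assert res["r_squared"] == pytest.approx(r_oracle)
        assert res["called_by_both"] == 5

    def test_category_counts(self):
        pool = np.array([0.1, 0.0, 0.2, 0.0])
        array = np.array([0.1, 0.3, 0.0, 0.0])
        res = pooled_maf_concordance(pool, array)
        assert (res["called_by_both"], res["pool_only"], res["array_only"]) == (1, 1, 1)

    def test_single_point_undefined(self):
        res = pooled_maf_concordance(np.array([0.1, 0.0]), np.array([0.1, 0.0]))
        assert res["r_squared"] is None


class TestIndelConcordance:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["ref_id", "pos", "kind", "maf"])

    def test_identical_sets_fully_detected(self):
        ind = self._frame([("r", 10, "DEL1", 0.1), ("r", 20, "INS1", 0.2)])
        res = indel_concordance(ind.copy(), ind)
        assert res["detection_fraction"] == 100.0

    def test_eight_of_ten_detected(self):
        ind = self._frame([("r", 10 * i, "DEL1", 0.1) for i in range(1, 11)])
        pool = self._frame([("r", 10 * i, "DEL1", 0.1) for i in range(1, 9)])
        res = indel_concordance(pool, ind)
        assert res["n_truth"] == 10 and res["n_detected"] == 8
        assert res["detection_fraction"] == pytest.approx(80.0)

    def test_maf_r2_over_detected_sites(self):
        ind = self._frame([("r", i, "DEL1", 0.05 * i) for i in range(1, 7)])
        pool = self._frame([("r", i, "DEL1", 0.05 * i + 0.01) for i in range(1, 7)])
        res = indel_concordance(pool, ind)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-9)
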