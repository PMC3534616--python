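"""Comparing sequencing calls against array-genotype truth.

Array genotypes (AA / AB / BB on the chip's two-allele axis) serve as the
validated truth set.  The headline accuracy statistics are genotype-level:

* sensitivity = 100 x (het called het + hom-var called hom-var)
                / (array het + array hom-var)
* specificity = 100 x (hom-WT called hom-WT) / (array hom-WT)

so calling a true hom-variant site heterozygous counts *against* sensitivity
— exact-genotype agreement, not mere variant presence.  Reports are
stratified by per-chromosome coverage threshold and by rarity bins defined on
cohort variant-allele counts (rare: <= 9 variant alleles; the 2% bin holds
sites with exactly 4 alleles, the 0.5% bin sites with exactly 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .individual_caller import HET, HOM_ALT, HOM_REF, NO_CALL

RARE_MAX_ALLELES = 9
COVERAGE_THRESHOLDS = (3, 5, 10, 15, 20)


@dataclass
class ArrayGenotypeTable:
    """Sample x position genotype matrix from a validation array export.

    ``genotypes`` holds codes (0 hom-ref/AA, 1 het/AB, 2 hom-alt/BB,
    -1 no-call) with one row per position, one column per sample.
    """

    positions: pd.DataFrame        # columns: ref_id, pos, ref, alt
    genotypes: np.ndarray          # (n_positions, n_samples) int8
    samples: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.positions), len(self.samples)):
            raise ValueError("genotype matrix shape does not match positions x samples")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def variant_allele_counts(self) -> np.ndarray:
        g = self.genotypes
        return np.where(g > 0, g, 0).sum(axis=1)

    def called_allele_counts(self) -> np.ndarray:
        return 2 * (self.genotypes >= 0).sum(axis=1)

    def mafs(self) -> np.ndarray:
        """Cohort variant-allele frequency; no-call alleles leave the denominator."""
        called = self.called_allele_counts()
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, self.variant_allele_counts() / called, np.nan)

    def to_tsv(self, path: str) -> None:
        df = self.positions.copy()
        code = {HOM_REF: "AA", HET: "AB", HOM_ALT: "BB", NO_CALL: "NC"}
        for j, s in enumerate(self.samples):
            df[s] = [code[int(g)] for g in self.genotypes[:, j]]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "ArrayGenotypeTable":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["ref_id", "pos", "ref", "alt"]
        samples = [c for c in df.columns if c not in meta_cols]
        decode = {"AA": HOM_REF, "AB": HET, "BB": HOM_ALT, "NC": NO_CALL}
        geno = np.array(
            [[decode[v] for v in df[s]] for s in samples], dtype=np.int8
        ).T
        return cls(df[meta_cols].reset_index(drop=True), geno, samples)


# --------------------------------------------------------------- site filters

def filter_positions_pooled(
    table: ArrayGenotypeTable,
    coverage_per_allele: np.ndarray,
    min_coverage_per_allele: float = 20.0,
) -> np.ndarray:
    """Eligibility mask for the pooled comparison.

    Drops positions with any cohort no-call, positions under the per-allele
    coverage floor, positions with ambiguous ref/alt designation, and chip
    duplicates (first kept).  Order of the individual filters is immaterial —
    each is an independent predicate and the mask is their conjunction.
    """
    cov = np.asarray(coverage_per_allele, dtype=float)
    full_call = (table.genotypes >= 0).all(axis=1)
    covered = cov >= min_coverage_per_allele
    pos_df = table.positions
    unambiguous = (
        pos_df["ref"].isin(list("ACGT")) & pos_df["alt"].isin(list("ACGT"))
        & (pos_df["ref"] != pos_df["alt"])
    ).to_numpy()
    not_dup = ~pos_df.duplicated(subset=["ref_id", "pos"]).to_numpy()
    return full_call & covered & unambiguous & not_dup


def filter_positions_indexed(
    table: ArrayGenotypeTable,
    calls: pd.DataFrame,
    window: int = 15,
) -> np.ndarray:
    """Per-sample eligibility matrix for the indexed comparison.

    ``calls`` needs columns sample, ref_id, pos, kind (SNV/INS1/DEL1).  An
    INDEL called within +/-``window`` bp of an array position in *any*
    individual discards the position cohort-wide; a SNV called within the
    window (but not at the position itself) discards it for that individual
    only.  Chip duplicates are dropped cohort-wide (first kept).
    """
    n_pos, n_samp = table.genotypes.shape
    eligible = np.ones((n_pos, n_samp), dtype=bool)
    not_dup = ~table.positions.duplicated(subset=["ref_id", "pos"]).to_numpy()
    eligible &= not_dup[:, None]
    sample_idx = {s: j for j, s in enumerate(table.samples)}
    arr_pos = table.positions["pos"].to_numpy()
    arr_ref = table.positions["ref_id"].to_numpy()
    for row in calls.itertuples(index=False):
        near = (arr_ref == row.ref_id) & (np.abs(arr_pos - row.pos) <= window)
        if row.kind in ("INS1", "DEL1"):
            eligible[near, :] = False
        else:
            near &= arr_pos != row.pos  # a SNV call at the position itself is the comparison, not an exclusion
            j = sample_idx.get(row.sample)
            if j is not None:
                eligible[near, j] = False
    return eligible


# ----------------------------------------------------------- accuracy metrics

def sensitivity_specificity(
    truth: np.ndarray, called: np.ndarray, as_percent: bool = True
) -> dict:
    """Genotype-level accuracy of ``called`` against array ``truth``.

    Inputs are aligned arrays of genotype codes (any shape); cells with truth
    NO_CALL are ignored.  Empty strata yield None rather than 0.
    """
    t = np.asarray(truth).ravel()
    c = np.asarray(called).ravel()
    valid = t != NO_CALL
    t, c = t[valid], c[valid]
    n_het = int((t == HET).sum())
    n_homalt = int((t == HOM_ALT).sum())
    n_homref = int((t == HOM_REF).sum())
    tp = int(((t == HET) & (c == HET)).sum() + ((t == HOM_ALT) & (c == HOM_ALT)).sum())
    tn = int(((t == HOM_REF) & (c == HOM_REF)).sum())
    scale = 100.0 if as_percent else 1.0
    sens = scale * tp / (n_het + n_homalt) if (n_het + n_homalt) else None
    spec = scale * tn / n_homref if n_homref else None
    return {
        "het_sites": n_het,
        "hom_alt_sites": n_homalt,
        "hom_ref_sites": n_homref,
        "matched_variant_sites": tp,
        "matched_hom_ref_sites": tn,
        "sensitivity": sens,
        "specificity": spec,
    }


def stratified_report(
    truth: np.ndarray,
    called: np.ndarray,
    depth: np.ndarray,
    allele_counts: np.ndarray,
    coverage_thresholds: tuple[int, ...] = COVERAGE_THRESHOLDS,
    diploid_depth_factor: int = 2,
) -> pd.DataFrame:
    """Accuracy table stratified by per-chromosome coverage and rarity bin.

    ``truth``/``called``/``depth`` are (positions, samples) matrices and
    ``allele_counts`` the cohort variant-allele count per position.  A cell
    enters the ``>=c`` stratum when its read depth reaches
    ``diploid_depth_factor * c`` (c-fold per chromosome for a diploid).
    """
    bins = {
        "all": np.ones(len(allele_counts), dtype=bool),
        "maf<=5%": allele_counts <= RARE_MAX_ALLELES,
        "2% (4 alleles)": allele_counts == 4,
        "0.5% (1 allele)": allele_counts == 1,
    }
    rows = []
    for c in coverage_thresholds:
        deep = depth >= diploid_depth_factor * c
        for bin_name, bin_mask in bins.items():
            cell = deep & bin_mask[:, None]
            t = np.where(cell, truth, NO_CALL)
            res = sensitivity_specificity(t, called)
            rows.append({"coverage": c, "maf_bin": bin_name, **res})
    return pd.DataFrame(rows)


def pooled_maf_concordance(
    pool_mafs: np.ndarray, array_mafs: np.ndarray
) -> dict:
    """R-squared of pooled vs array MAFs over positions variant in either.

    ``pool_mafs`` uses 0 (or NaN) for positions the pool caller did not call.
    Also reports how many positions each method called polymorphic.
    """
    p = np.nan_to_num(np.asarray(pool_mafs, dtype=float), nan=0.0)
    a = np.nan_to_num(np.asarray(array_mafs, dtype=float), nan=0.0)
    either = (p > 0) | (a > 0)
    n = int(either.sum())
    out = {
        "n_positions": n,
        "called_by_both": int(((p > 0) & (a > 0)).sum()),
        "pool_only": int(((p > 0) & (a == 0)).sum()),
        "array_only": int(((p == 0) & (a > 0)).sum()),
        "r_squared": None,
    }
    if n >= 2 and np.ptp(a[either]) > 0 and np.ptp(p[either]) > 0:
        res = stats.linregress(a[either], p[either])
        out["r_squared"] = float(res.rvalue**2)
    return out


def indel_concordance(
    pool_calls: pd.DataFrame, individual_calls: pd.DataFrame
) -> dict:
    """Pool detection rate of individually-called 1 bp indel sites, plus MAF R2.

    Both frames need ref_id, pos, kind and maf columns; ``individual_calls``
    is the aggregated per-individual truth restricted upstream to adequately
    covered 1 bp indels.
    """
    key = ["ref_id", "pos", "kind"]
    ind = individual_calls[individual_calls["kind"].isin(["INS1", "DEL1"])]
    pool = pool_calls[pool_calls["kind"].isin(["INS1", "DEL1"])]
    truth_sites = ind.drop_duplicates(subset=key)
    merged = truth_sites.merge(pool, on=key, how="left", suffixes=("_ind", "_pool"))
    detected = merged["maf_pool"].notna()
    out = {
        "n_truth": len(truth_sites),
        "n_detected": int(detected.sum()),
        "detection_fraction": 100.0 * detected.mean() if len(truth_sites) else None,
        "r_squared": None,
    }
    sub = merged[detected]
    if len(sub) >= 2 and sub["maf_ind"].nunique() > 1 and sub["maf_pool"].nunique() > 1:
        res = stats.linregress(sub["maf_ind"], sub["maf_pool"])
        out["r_squared"] = float(res.rvalue**2)
    return out
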