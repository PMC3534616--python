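"""Capture-efficiency and variant-quality summaries.

Mirrors the standard hybrid-selection report: duplication, on-target and
on/near-target base fractions (near = within 250 bp of an interval), fold
enrichment of the targeted fraction of the genome, coverage histograms at the
usual thresholds, inter-sample interval-rank concordance, Ti/Tv and a
descriptive GC/coverage table.  Fold enrichment here is the on-target base
fraction divided by the target's share of the genome (a base-fraction
definition; tool-specific variants of the denominator differ).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .reads import AlignedReadSet

NEAR_TARGET_BP = 250
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class CaptureMetrics:
    total_reads: int
    aligned_percent: float
    duplicate_percent: float
    on_target_percent: float          # of aligned, non-duplicate bases
    on_near_target_percent: float
    fold_enrichment: float
    mean_target_coverage: float
    pct_bases_at: dict[int, float]    # % target bases >= threshold
    overall_on_target_percent: float  # aligned% x on-target% / 100

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_reads", self.total_reads),
            ("aligned_%", self.aligned_percent),
            ("duplicate_%", self.duplicate_percent),
            ("on_target_%", self.on_target_percent),
            ("on_near_target_%", self.on_near_target_percent),
            ("fold_enrichment", self.fold_enrichment),
            ("mean_target_coverage", self.mean_target_coverage),
            ("overall_on_target_%", self.overall_on_target_percent),
        ] + [(f"pct_bases_ge_{c}", v) for c, v in self.pct_bases_at.items()]
        return pd.DataFrame(rows, columns=["metric", "value"])


def overall_on_target(aligned_percent: float, on_target_percent: float) -> float:
    """Share of *raw* data that ends up on target: the product identity."""
    return aligned_percent * on_target_percent / 100.0


def target_masks(targets: list[tuple[int, int]], genome_size: int, near_bp: int = NEAR_TARGET_BP):
    """Boolean on-target and on/near-target masks from 1-based inclusive intervals."""
    if not targets:
        raise ValueError("empty target list")
    on = np.zeros(genome_size, dtype=bool)
    near = np.zeros(genome_size, dtype=bool)
    for start1, end1 in targets:
        on[start1 - 1 : end1] = True
        near[max(0, start1 - 1 - near_bp) : min(genome_size, end1 + near_bp)] = True
    return on, near


def compute_metrics(
    reads: AlignedReadSet,
    targets: list[tuple[int, int]],
    genome_size: int | None = None,
    total_reads: int | None = None,
    thresholds: tuple[int, ...] = (3, 5, 10, 15, 20),
) -> CaptureMetrics:
    """Capture metrics for one aligned sample.

    ``total_reads`` is the raw read count before alignment (defaults to the
    aligned count, i.e. aligned fraction 100%).  Duplicates must be flagged
    on the read set (``mark_duplicates`` flags exact coordinate+sequence
    copies if the simulator has not already).
    """
    genome_size = genome_size or len(reads.ref)
    n_aligned = reads.n_reads
    total = total_reads if total_reads is not None else n_aligned
    dup = reads.duplicate if reads.duplicate is not None else reads.mark_duplicates()
    n_dup = int(dup.sum())
    keep = reads.subset(np.flatnonzero(~dup)) if n_dup else reads

    on, near = target_masks(targets, genome_size)
    depth = coverage_depth(keep, genome_size)
    total_bases = int(depth.sum())
    on_bases = int(depth[on].sum())
    near_bases = int(depth[near].sum())

    aligned_pct = 100.0 * n_aligned / total if total else 0.0
    on_pct = 100.0 * on_bases / total_bases if total_bases else 0.0
    near_pct = 100.0 * near_bases / total_bases if total_bases else 0.0
    target_frac = on.sum() / genome_size
    fold = (on_pct / 100.0) / target_frac if target_frac else float("nan")
    mean_cov = float(depth[on].mean()) if on.any() else float("nan")
    hist = coverage_histogram(depth[on], thresholds)
    return CaptureMetrics(
        total_reads=total,
        aligned_percent=aligned_pct,
        duplicate_percent=100.0 * n_dup / n_aligned if n_aligned else 0.0,
        on_target_percent=on_pct,
        on_near_target_percent=near_pct,
        fold_enrichment=fold,
        mean_target_coverage=mean_cov,
        pct_bases_at=hist,
        overall_on_target_percent=overall_on_target(aligned_pct, on_pct),
    )


def coverage_depth(reads: AlignedReadSet, genome_size: int) -> np.ndarray:
    """Per-base read depth over the reference (gap positions still covered)."""
    depth = np.zeros(genome_size + 1, dtype=np.int64)
    np.add.at(depth, reads.start, 1)
    np.add.at(depth, reads.start + reads.read_length, -1)
    return np.cumsum(depth)[:genome_size]


def coverage_histogram(
    depths: np.ndarray, thresholds: tuple[int, ...] = (3, 5, 10, 15, 20)
) -> dict[int, float]:
    """Percent of bases at or above each depth threshold (non-increasing)."""
    d = np.asarray(depths)
    n = d.size
    return {int(c): (100.0 * float((d >= c).sum()) / n if n else float("nan")) for c in thresholds}


def interval_rank_correlation(coverages: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pairwise R2 of per-interval coverage *ranks* between samples.

    ``coverages`` holds one column per sample, one row per target interval.
    Intervals with zero coverage in any sample are excluded first.  Returns
    the full pairwise matrix and the average off-diagonal R2.
    """
    df = coverages.loc[(coverages > 0).all(axis=1)]
    samples = list(df.columns)
    if len(samples) < 2 or len(df) < 2:
        raise ValueError("need >=2 samples and >=2 jointly covered intervals")
    ranks = df.rank(ascending=False, method="average")
    mat = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    vals = []
    for a, b in combinations(samples, 2):
        r = stats.pearsonr(ranks[a], ranks[b]).statistic
        mat.loc[a, b] = mat.loc[b, a] = r**2
        vals.append(r**2)
    return mat, float(np.mean(vals))


def titv_ratio(calls: list[tuple[str, str]] | pd.DataFrame) -> float | None:
    """Transition/transversion ratio of an SNV call set (None if undefined)."""
    if isinstance(calls, pd.DataFrame):
        pairs = list(zip(calls["ref"], calls["alt"]))
    else:
        pairs = list(calls)
    pairs = [(r, a) for r, a in pairs if r in "ACGT" and a in "ACGT" and r != a]
    if not pairs:
        return None
    ti = sum((r, a) in TRANSITIONS for r, a in pairs)
    tv = len(pairs) - ti
    return ti / tv if tv else None


def gc_coverage_summary(
    gc_fraction: np.ndarray, coverage: np.ndarray, bin_width: float = 0.05
) -> pd.DataFrame:
    """Coverage distribution statistics per GC-content bin (descriptive)."""
    gc = np.asarray(gc_fraction, dtype=float)
    cov = np.asarray(coverage, dtype=float)
    if gc.shape != cov.shape:
        raise ValueError("gc and coverage arrays differ in length")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    which = np.clip(np.digitize(gc, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            {
                "gc_lo": edges[b],
                "gc_hi": edges[b + 1],
                "n_baits": int(sel.sum()),
                "mean_coverage": float(cov[sel].mean()),
                "median_coverage": float(np.median(cov[sel])),
            }
        )
    return pd.DataFrame(rows)
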