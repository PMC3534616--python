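"""Rare-variant calling in anonymous DNA pools.

The caller tests, at every pileup column and separately on each strand,
whether the count of a candidate alternate allele exceeds what the calibrated
sequencing error model can explain.  Under the null, each of the ``n`` reads
on a strand errs toward the alternate allele independently with its own
cycle-specific model rate, so the alt-read count follows a Poisson-binomial
distribution; the reported statistic is the exact upper-tail probability
P(X >= k_obs), computed by convolving the per-cycle binomial distributions
(exact at any depth).  A variant is emitted only when the complementary base
change passes the log10 p-value cutoff on *both* strands — the signature
that separates real pool alleles from strand-specific artifacts.

The minor allele frequency of a passing call is reported on the pool grid
k/(2N): the error-corrected pooled alt fraction is rounded to the nearest
allele count k in [1, 2N].
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .error_model import ErrorModel
from .reads import AlignedReadSet
from .seq import BASES, GAP_CODE

logger = logging.getLogger(__name__)

ALLELE_DEL = 4
ALLELE_INS = 5
_LOG10_FLOOR = -320.0


@dataclass
class PoolCallerParams:
    cutoff: float = -1.3          # log10 p-value cutoff, both strands must pass
    two_n: int = 200              # allele count in the pool
    max_mismatches: int = 5
    trim_length: int = 80
    min_alt_reads: int = 1

    def __post_init__(self) -> None:
        if self.cutoff >= 0:
            raise ValueError("log10 p-value cutoff must be negative")
        if self.two_n < 2:
            raise ValueError("pool allele count must be >= 2")


@dataclass
class PileupColumn:
    """Per-position allele counts stratified by strand and sequencing cycle."""

    ref_id: str
    pos: int                      # 1-based
    ref: int                      # 0..3
    counts: np.ndarray            # (2, L, 6): A,C,G,T, 1bp-del, 1bp-ins

    def depth(self, strand: int) -> int:
        # deletion observations cover the position; insertions do not
        return int(self.counts[strand, :, :5].sum())

    def allele_total(self, allele: int) -> int:
        return int(self.counts[:, :, allele].sum())

    def strand_trials(self, strand: int) -> np.ndarray:
        """Called-base count per cycle on one strand (Bernoulli trials)."""
        return self.counts[strand, :, :4].sum(axis=1)


@dataclass
class PoolVariantCall:
    ref_id: str
    pos: int
    ref: str
    alt: str
    kind: str                     # SNV / DEL1 / INS1
    log10_p_fwd: float
    log10_p_rev: float
    k: int
    maf: float
    depth_fwd: int
    depth_rev: int
    both_strands_pass: bool = True


def compress_reads(seqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical read sequences to unique records with multiplicities.

    Input is an (n, L) base-code matrix; output preserves first-occurrence
    order.  Downstream calling uses unique reads only; the multiplicity is
    retained for reporting.
    """
    seqs = np.atleast_2d(np.ascontiguousarray(seqs, dtype=np.uint8))
    view = seqs.view(np.dtype((np.void, seqs.shape[1]))).ravel()
    _, first, counts = np.unique(view, return_index=True, return_counts=True)
    order = np.argsort(first)
    return seqs[first[order]], counts[order]


def trim_reads(reads: AlignedReadSet, trim_length: int) -> AlignedReadSet:
    """Trim every read to its first ``trim_length`` sequencing cycles.

    For reverse-strand rows the early cycles sit at the 3' end in reference
    orientation, so the kept window and the start coordinate shift.
    """
    L = reads.read_length
    t = trim_length
    if t >= L:
        return reads
    fwd = reads.strand == 0
    seq = np.where(fwd[:, None], reads.seq[:, :t], reads.seq[:, L - t :])
    start = np.where(fwd, reads.start, reads.start + (L - t))
    keep_ins = (
        reads.insertions[
            np.where(
                fwd[reads.insertions[:, 0]],
                reads.insertions[:, 1] < t,
                reads.insertions[:, 1] >= L - t,
            )
        ].copy()
        if reads.insertions.shape[0]
        else reads.insertions
    )
    if keep_ins.shape[0]:
        keep_ins[:, 1] = np.where(
            fwd[keep_ins[:, 0]], keep_ins[:, 1], keep_ins[:, 1] - (L - t)
        )
    return AlignedReadSet(
        ref_name=reads.ref_name,
        ref=reads.ref,
        seq=np.ascontiguousarray(seq),
        start=start,
        strand=reads.strand,
        names=reads.names,
        insertions=keep_ins,
        duplicate=reads.duplicate,
    )


def build_pileup(
    reads: AlignedReadSet,
    targets: list[tuple[int, int]] | None = None,
    excluded_cycles: set[int] | frozenset[int] = frozenset(),
    flank: int = 101,
) -> list[PileupColumn]:
    """Strand/cycle-stratified pileup restricted to target intervals + flank.

    ``targets`` are 1-based inclusive intervals on the read set's reference
    (None means the whole reference).  Base calls at excluded cycles are
    masked and contribute nothing — neither mismatches nor coverage.
    """
    R = len(reads.ref)
    L = reads.read_length
    in_target = np.zeros(R, dtype=bool)
    if targets is None:
        in_target[:] = True
    else:
        for start1, end1 in targets:
            lo = max(0, start1 - 1 - flank)
            hi = min(R, end1 + flank)
            in_target[lo:hi] = True
    col_pos = np.flatnonzero(in_target)          # 0-based positions kept
    col_of = np.full(R, -1, dtype=np.int64)
    col_of[col_pos] = np.arange(col_pos.size)
    ncols = col_pos.size

    counts = np.zeros((ncols, 2, L, 6), dtype=np.int32)
    cyc_ok = np.ones(L + 1, dtype=bool)
    for c in excluded_cycles:
        if 1 <= c <= L:
            cyc_ok[c] = False

    offs = np.arange(L)
    flat = counts.reshape(-1)
    for lo in range(0, reads.n_reads, 100_000):
        hi = min(lo + 100_000, reads.n_reads)
        start = reads.start[lo:hi]
        strand = reads.strand[lo:hi].astype(np.int64)
        blk = reads.seq[lo:hi]
        pos = start[:, None] + offs
        cyc = np.where(strand[:, None] == 0, offs + 1, L - offs)
        cols = col_of[pos]
        allele = np.where(blk == GAP_CODE, ALLELE_DEL, blk).astype(np.int64)
        ok = (cols >= 0) & cyc_ok[cyc] & (allele <= ALLELE_DEL)
        s_mat = np.broadcast_to(strand[:, None], blk.shape)
        idx = (((cols * 2 + s_mat) * L) + (cyc - 1)) * 6 + allele
        np.add.at(flat, idx[ok], 1)

    if reads.insertions.shape[0]:
        r = reads.insertions[:, 0]
        off = reads.insertions[:, 1]
        pos = reads.start[r] + off
        strand = reads.strand[r].astype(np.int64)
        cyc = np.where(strand == 0, off + 1, L - off)
        cols = col_of[pos]
        ok = (cols >= 0) & cyc_ok[cyc]
        idx = (((cols * 2 + strand) * L) + (cyc - 1)) * 6 + ALLELE_INS
        np.add.at(flat, idx[ok], 1)

    return [
        PileupColumn(reads.ref_name, int(p) + 1, int(reads.ref[p]), counts[i])
        for i, p in enumerate(col_pos)
    ]


def _binom_pmf(n: int, p: float) -> np.ndarray:
    """Binomial(n, p) pmf by stable recurrence (no special-function calls)."""
    if n == 0:
        return np.array([1.0])
    if p <= 0:
        out = np.zeros(n + 1)
        out[0] = 1.0
        return out
    if p >= 1:
        out = np.zeros(n + 1)
        out[n] = 1.0
        return out
    k = np.arange(n + 1)
    logpmf = (
        np.cumsum(np.concatenate([[0.0], np.log((n - k[:-1]) / (k[:-1] + 1))]))
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )
    return np.exp(logpmf)


def poisson_binomial_tail(trials: np.ndarray, probs: np.ndarray, k_obs: int) -> float:
    """Exact P(X >= k_obs) for X = sum of Binomial(trials_c, probs_c).

    Convolves the per-group binomial pmfs; exact for any total depth that
    fits in memory (thousands of reads), which covers every desk-scale pool.
    """
    if k_obs <= 0:
        return 1.0
    pmf = np.array([1.0])
    for n_c, p_c in zip(trials, probs):
        if n_c <= 0:
            continue
        pmf = np.convolve(pmf, _binom_pmf(int(n_c), float(p_c)))
    if k_obs >= pmf.size:
        return 0.0
    return float(pmf[k_obs:].sum())


def strand_pvalue(
    column: PileupColumn, strand: int, alt: int, model: ErrorModel
) -> float:
    """log10 upper-tail p-value for the alt count on one strand.

    The per-read null error probability is the model's cycle-specific rate
    toward ``alt`` given the column's reference base.
    """
    if alt == column.ref:
        raise ValueError("alt equals the reference base")
    trials = column.strand_trials(strand)
    if trials.sum() == 0:
        raise ValueError("zero depth on requested strand")
    k_obs = int(column.counts[strand, :, alt].sum())
    rates = model.rates()[strand, :, column.ref, alt]
    tail = poisson_binomial_tail(trials, rates, k_obs)
    return float(np.log10(tail)) if tail > 0 else _LOG10_FLOOR


def _indel_strand_pvalue(
    column: PileupColumn, strand: int, kind: str, model: ErrorModel
) -> float:
    allele = ALLELE_DEL if kind == "del" else ALLELE_INS
    trials = column.counts[strand, :, :5].sum(axis=1)
    if trials.sum() == 0:
        raise ValueError("zero depth on requested strand")
    k_obs = int(column.counts[strand, :, allele].sum())
    pc = model.pseudocount
    kidx = 0 if kind == "del" else 1
    rates = (model.indel_counts[strand, :, kidx] + pc) / (
        model.opp[strand].sum(axis=1) + 4 * pc
    )
    tail = poisson_binomial_tail(trials, rates, k_obs)
    return float(np.log10(tail)) if tail > 0 else _LOG10_FLOOR


def estimate_maf(
    column: PileupColumn, alt: int, model: ErrorModel, two_n: int
) -> tuple[int, float]:
    """Pool-constrained MAF: error-corrected alt fraction snapped to k/(2N)."""
    if alt >= 4:
        trials = column.counts[:, :, :5].sum(axis=2)
        k_obs = column.counts[:, :, alt].sum()
        pc = model.pseudocount
        kidx = 0 if alt == ALLELE_DEL else 1
        rates = np.stack(
            [
                (model.indel_counts[s, :, kidx] + pc) / (model.opp[s].sum(axis=1) + 4 * pc)
                for s in range(2)
            ]
        )
    else:
        trials = np.stack([column.strand_trials(s) for s in range(2)])
        k_obs = column.counts[:, :, alt].sum()
        rates = model.rates()[:, :, column.ref, alt]
    total = trials.sum()
    if total == 0:
        return 1, 1.0 / two_n
    f = float(k_obs) / total
    expected_err = float((trials * rates).sum()) / total
    f_hat = max(f - expected_err, 0.0)
    k = int(np.clip(round(two_n * f_hat), 1, two_n))
    return k, k / two_n


def _best_alt(column: PileupColumn) -> int | None:
    totals = column.counts[:, :, :4].sum(axis=(0, 1))
    totals[column.ref] = 0
    if totals.sum() == 0:
        return None
    best = int(totals.argmax())  # argmax breaks count ties at the lowest index,
    return best                  # i.e. lexicographically first allele


def call_pool_variants(
    pileup: list[PileupColumn],
    model: ErrorModel,
    params: PoolCallerParams,
) -> tuple[list[PoolVariantCall], pd.DataFrame]:
    """Both-strand SNV calling over a pileup; also emits coverage-mode rows.

    A site with zero depth on either strand cannot be called (the
    complementary base change cannot be confirmed there); such sites appear
    in the coverage output but never as calls.
    """
    calls: list[PoolVariantCall] = []
    cov_rows = []
    for col in pileup:
        d_f, d_r = col.depth(0), col.depth(1)
        cov_rows.append((col.ref_id, col.pos, BASES[col.ref], d_f, d_r))
        if d_f == 0 or d_r == 0:
            continue
        alt = _best_alt(col)
        if alt is None or col.allele_total(alt) < params.min_alt_reads:
            continue
        lp_f = strand_pvalue(col, 0, alt, model)
        lp_r = strand_pvalue(col, 1, alt, model)
        if lp_f <= params.cutoff and lp_r <= params.cutoff:
            k, maf = estimate_maf(col, alt, model, params.two_n)
            calls.append(
                PoolVariantCall(
                    col.ref_id, col.pos, BASES[col.ref], BASES[alt], "SNV",
                    lp_f, lp_r, k, maf, d_f, d_r,
                )
            )
    coverage = pd.DataFrame(
        cov_rows, columns=["ref_id", "pos", "ref", "depth_fwd", "depth_rev"]
    )
    return calls, coverage


def call_pool_indels_1bp(
    pileup: list[PileupColumn],
    model: ErrorModel,
    params: PoolCallerParams,
) -> list[PoolVariantCall]:
    """1 bp insertion/deletion calling with the same both-strand machinery."""
    calls: list[PoolVariantCall] = []
    for col in pileup:
        d_f, d_r = col.depth(0), col.depth(1)
        if d_f == 0 or d_r == 0:
            continue
        for kind, allele in (("del", ALLELE_DEL), ("ins", ALLELE_INS)):
            if col.allele_total(allele) < params.min_alt_reads:
                continue
            lp_f = _indel_strand_pvalue(col, 0, kind, model)
            lp_r = _indel_strand_pvalue(col, 1, kind, model)
            if lp_f <= params.cutoff and lp_r <= params.cutoff:
                k, maf = estimate_maf(col, allele, model, params.two_n)
                calls.append(
                    PoolVariantCall(
                        col.ref_id, col.pos, BASES[col.ref],
                        "-" if kind == "del" else "+?",
                        "DEL1" if kind == "del" else "INS1",
                        lp_f, lp_r, k, maf, d_f, d_r,
                    )
                )
    return calls


def calls_to_frame(calls: list[PoolVariantCall]) -> pd.DataFrame:
    cols = [
        "ref_id", "pos", "ref", "alt", "kind", "log10_p_fwd", "log10_p_rev",
        "k", "maf", "depth_fwd", "depth_rev",
    ]
    return pd.DataFrame([[getattr(c, f) for f in cols] for c in calls], columns=cols)
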