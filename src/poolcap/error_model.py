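"""Per-cycle, per-strand, per-substitution sequencing error model.

The model is estimated from aligned reads of a variant-free control sequence
(a PhiX174-style spike-in or a validated invariant locus).  For every cell
(strand, cycle, [preceding reference base,] template base -> observed base)
it stores mismatch and opportunity counts; rates are pseudocount-smoothed:

    rate = (mismatches + pseudocount) / (opportunities + 4 * pseudocount)

so no rate is ever exactly zero.  A "second order" model (order=2) further
stratifies each cell by the preceding reference base (4 contexts); lookups
fall back to the context-marginal (order-1) rate when a context cell has no
opportunities.

The *cumulative* per-cycle error — the sum of all 12 substitution-type rates,
context-marginalized — is the quantity used to discard aberrant sequencing
cycles: a cycle whose cumulative rate exceeds the threshold (0.02% by
default) on either strand is excluded from variant calling.

A single pooled 1 bp indel error rate per (strand, cycle) is estimated the
same way from gap/insertion observations in the control alignment, since the
substitution model says nothing about indel error.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads import AlignedReadSet
from .seq import BASES, GAP_CODE

logger = logging.getLogger(__name__)

DEFAULT_CYCLE_THRESHOLD = 0.0002  # cumulative per-cycle rate, as a fraction (0.02%)

_STRANDS = ("forward", "reverse")


@dataclass
class ErrorModel:
    read_length: int
    order: int = 1
    pseudocount: float = 1.0
    # order-1 (context-marginal) tensors, always present
    mism: np.ndarray = None          # (2, L, 4, 4) int64, diag zero
    opp: np.ndarray = None           # (2, L, 4) int64
    # order-2 tensors when order == 2
    mism2: np.ndarray | None = None  # (2, L, 4 ctx, 4, 4)
    opp2: np.ndarray | None = None   # (2, L, 4 ctx, 4)
    indel_counts: np.ndarray = None  # (2, L, 2) int64: [del, ins] observations
    excluded: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        L = self.read_length
        if self.mism is None:
            self.mism = np.zeros((2, L, 4, 4), dtype=np.int64)
        if self.opp is None:
            self.opp = np.zeros((2, L, 4), dtype=np.int64)
        if self.indel_counts is None:
            self.indel_counts = np.zeros((2, L, 2), dtype=np.int64)
        if self.order == 2 and self.mism2 is None:
            self.mism2 = np.zeros((2, L, 4, 4, 4), dtype=np.int64)
            self.opp2 = np.zeros((2, L, 4, 4), dtype=np.int64)

    # ------------------------------------------------------------------ rates
    def rates(self) -> np.ndarray:
        """Order-1 rate tensor (2, L, 4 ref, 4 obs); diagonal is meaningless."""
        pc = self.pseudocount
        return (self.mism + pc) / (self.opp[..., None] + 4 * pc)

    def error_rate(
        self, strand: int, cycle: int, ref: int, obs: int, context: int | None = None
    ) -> float:
        """Error probability for one cell; order-2 context falls back to order-1."""
        if cycle in self.excluded:
            raise ValueError(f"cycle {cycle} is excluded; mask it before lookup")
        if obs == ref:
            raise ValueError("observed base equals the template base; not an error cell")
        if not (1 <= cycle <= self.read_length):
            raise ValueError(f"cycle {cycle} outside 1..{self.read_length}")
        pc = self.pseudocount
        if self.order == 2 and context is not None:
            opp = self.opp2[strand, cycle - 1, context, ref]
            if opp > 0:
                mm = self.mism2[strand, cycle - 1, context, ref, obs]
                return float((mm + pc) / (opp + 4 * pc))
        mm = self.mism[strand, cycle - 1, ref, obs]
        opp = self.opp[strand, cycle - 1, ref]
        return float((mm + pc) / (opp + 4 * pc))

    def indel_rate(self, strand: int, cycle: int, kind: str = "del") -> float:
        pc = self.pseudocount
        k = 0 if kind == "del" else 1
        cnt = self.indel_counts[strand, cycle - 1, k]
        opp = self.opp[strand, cycle - 1].sum()
        return float((cnt + pc) / (opp + 4 * pc))

    def cumulative_cycle_error(self) -> np.ndarray:
        """(2, L) sum of the 12 substitution-type rates per strand and cycle."""
        r = self.rates().copy()
        for b in range(4):
            r[:, :, b, b] = 0.0
        return r.sum(axis=(2, 3))

    def excluded_cycles(self, threshold: float = DEFAULT_CYCLE_THRESHOLD) -> set[int]:
        """Cycles whose cumulative error exceeds ``threshold`` on either strand."""
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        cum = self.cumulative_cycle_error()
        bad = np.flatnonzero((cum > threshold).any(axis=0)) + 1
        self.excluded = set(int(c) for c in bad)
        kept = self.read_length - len(self.excluded)
        logger.info(
            "cycle exclusion: %d of %d cycles above %.4g, %d retained",
            len(self.excluded), self.read_length, threshold, kept,
        )
        return set(self.excluded)

    # ---------------------------------------------------------------- file IO
    def to_tsv(self, path: str) -> None:
        """Serialize counts (bit-exact reload: rates are derived, not stored)."""
        rows = []
        for s in range(2):
            for c in range(self.read_length):
                for ref in range(4):
                    opp = int(self.opp[s, c, ref])
                    for obs in range(4):
                        if obs == ref:
                            continue
                        rows.append(
                            (_STRANDS[s], c + 1, ".", BASES[ref], BASES[obs],
                             int(self.mism[s, c, ref, obs]), opp)
                        )
                    if self.order == 2:
                        for ctx in range(4):
                            opp2 = int(self.opp2[s, c, ctx, ref])
                            for obs in range(4):
                                if obs == ref:
                                    continue
                                rows.append(
                                    (_STRANDS[s], c + 1, BASES[ctx], BASES[ref], BASES[obs],
                                     int(self.mism2[s, c, ctx, ref, obs]), opp2)
                                )
                for k, kind in enumerate(("del", "ins")):
                    rows.append(
                        (_STRANDS[s], c + 1, ".", "*", kind,
                         int(self.indel_counts[s, c, k]), int(self.opp[s, c].sum()))
                    )
        df = pd.DataFrame(
            rows, columns=["strand", "cycle", "context", "ref", "obs", "mismatches", "opportunities"]
        )
        df["rate"] = (df["mismatches"] + self.pseudocount) / (
            df["opportunities"] + 4 * self.pseudocount
        )
        with open(path, "w") as f:
            f.write(f"#read_length={self.read_length}\torder={self.order}"
                    f"\tpseudocount={self.pseudocount!r}\n")
            df.to_csv(f, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "ErrorModel":
        with open(path) as f:
            meta = f.readline().lstrip("#").strip().split("\t")
            kv = dict(item.split("=", 1) for item in meta)
            df = pd.read_csv(f, sep="\t")
        model = cls(
            read_length=int(kv["read_length"]),
            order=int(kv["order"]),
            pseudocount=float(kv["pseudocount"]),
        )
        sidx = {name: i for i, name in enumerate(_STRANDS)}
        bidx = {b: i for i, b in enumerate(BASES)}
        for row in df.itertuples(index=False):
            s, c = sidx[row.strand], int(row.cycle) - 1
            if row.ref == "*":
                k = 0 if row.obs == "del" else 1
                model.indel_counts[s, c, k] = row.mismatches
                continue
            ref, obs = bidx[row.ref], bidx[row.obs]
            if row.context == ".":
                model.mism[s, c, ref, obs] = row.mismatches
                model.opp[s, c, ref] = row.opportunities
            else:
                ctx = bidx[row.context]
                model.mism2[s, c, ctx, ref, obs] = row.mismatches
                model.opp2[s, c, ctx, ref] = row.opportunities
        return model


def build_error_model(
    control: AlignedReadSet,
    order: int = 1,
    pseudocount: float = 1.0,
    max_mismatches: int = 5,
    deduplicate: bool = True,
) -> ErrorModel:
    """Estimate an :class:`ErrorModel` from aligned control reads.

    Reads are first collapsed to unique (strand, start, sequence) records and
    reads with more than ``max_mismatches`` substitutions against the control
    reference are discarded before counting, so residual contaminant or
    misaligned reads do not inflate the rates.
    """
    if control.n_reads == 0:
        raise ValueError("no control reads")
    reads = control.unique()[0] if deduplicate else control
    mm = reads.mismatch_counts()
    keep = mm <= max_mismatches
    if not keep.all():
        logger.info("discarding %d control reads with >%d mismatches",
                    int((~keep).sum()), max_mismatches)
        reads = reads.subset(np.flatnonzero(keep))
    model = ErrorModel(read_length=reads.read_length, order=order, pseudocount=pseudocount)
    _accumulate(model, reads)
    zero_opp = int((model.opp.sum(axis=2) == 0).sum())
    if zero_opp:
        logger.warning(
            "%d (strand, cycle) cells have zero opportunities; their rates are "
            "pure pseudocount", zero_opp,
        )
    return model


def _accumulate(model: ErrorModel, reads: AlignedReadSet) -> None:
    L = reads.read_length
    offs = np.arange(L)
    ref = reads.ref
    for lo in range(0, reads.n_reads, 100_000):
        hi = min(lo + 100_000, reads.n_reads)
        start = reads.start[lo:hi]
        strand = reads.strand[lo:hi].astype(np.int64)
        blk = reads.seq[lo:hi]
        pos = start[:, None] + offs               # (n, L) reference positions
        refb = ref[pos]                           # template base per offset
        cyc = np.where(strand[:, None] == 0, offs + 1, L - offs)  # 1-based cycles
        s_mat = np.broadcast_to(strand[:, None], blk.shape)

        is_gap = blk == GAP_CODE
        is_base = blk < 4
        valid = is_base  # substitutions counted on called bases only

        # opportunities: every called base is an observation of (strand, cycle, ref)
        flat_opp = ((s_mat * L + (cyc - 1)) * 4 + refb)[valid]
        np.add.at(model.opp.reshape(-1), flat_opp, 1)

        mis = valid & (blk != refb)
        flat_mm = (((s_mat * L + (cyc - 1)) * 4 + refb) * 4 + blk)[mis]
        np.add.at(model.mism.reshape(-1), flat_mm, 1)

        # 1 bp indel error observations
        if is_gap.any():
            flat_del = (s_mat * L + (cyc - 1))[is_gap] * 2
            np.add.at(model.indel_counts.reshape(-1), flat_del, 1)

        if model.order == 2:
            ctx = ref[np.maximum(pos - 1, 0)]
            ctx_ok = valid & (pos >= 1)
            flat_opp2 = (((s_mat * L + (cyc - 1)) * 4 + ctx) * 4 + refb)[ctx_ok]
            np.add.at(model.opp2.reshape(-1), flat_opp2, 1)
            mis2 = mis & ctx_ok
            flat_mm2 = ((((s_mat * L + (cyc - 1)) * 4 + ctx) * 4 + refb) * 4 + blk)[mis2]
            np.add.at(model.mism2.reshape(-1), flat_mm2, 1)

    if reads.insertions.shape[0]:
        r = reads.insertions[:, 0]
        off = reads.insertions[:, 1]
        strand = reads.strand[r].astype(np.int64)
        cyc = np.where(strand == 0, off + 1, L - off)
        np.add.at(model.indel_counts.reshape(-1), (strand * L + (cyc - 1)) * 2 + 1, 1)


def cumulative_cycle_error(model: ErrorModel) -> np.ndarray:
    """Functional alias for :meth:`ErrorModel.cumulative_cycle_error`."""
    return model.cumulative_cycle_error()


def excluded_cycles(model: ErrorModel, threshold: float = DEFAULT_CYCLE_THRESHOLD) -> set[int]:
    """Functional alias for :meth:`ErrorModel.excluded_cycles`."""
    return model.excluded_cycles(threshold)
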