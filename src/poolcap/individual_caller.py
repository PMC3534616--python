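"""Minimal diploid genotyper for demultiplexed, duplicate-removed samples.

The genotype at a biallelic site is the maximum-likelihood choice among
hom-ref, het and hom-alt under a symmetric binomial read model (alt-read
probability e, 0.5 and 1-e respectively).  Two post-processing rules mirror
the standard short-read pipeline this replaces:

* a variant genotype additionally requires ``min_alt_reads`` supporting reads;
* a heterozygous call in which fewer than 20% of the informative reads match
  the reference (resp. the variant) allele is reclassified to homozygous
  variant (resp. homozygous wild type).

Likelihood ties break toward the genotype with fewer variant alleles.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pool_caller import PileupColumn

HOM_REF, HET, HOM_ALT, NO_CALL = 0, 1, 2, -1
_GENOTYPE_NAMES = {HOM_REF: "hom-ref", HET: "het", HOM_ALT: "hom-alt", NO_CALL: "no-call"}


@dataclass
class GenotypeCall:
    ref_id: str
    pos: int
    genotype: int                # HOM_REF / HET / HOM_ALT / NO_CALL
    depth: int
    alt_fraction: float
    ref_reads: int = 0
    alt_reads: int = 0
    passed_filters: bool = True

    @property
    def genotype_name(self) -> str:
        return _GENOTYPE_NAMES[self.genotype]


def genotype_counts(
    ref_reads: np.ndarray,
    alt_reads: np.ndarray,
    min_alt_reads: int = 2,
    base_error: float = 0.005,
) -> np.ndarray:
    """Vectorized ML genotyping from per-site ref/alt read counts.

    Returns an int8 array of genotype codes; zero-depth cells are NO_CALL.
    Only reads matching one of the two alleles are informative.
    """
    shape = np.shape(ref_reads)
    r = np.atleast_1d(np.asarray(ref_reads, dtype=np.int64))
    a = np.atleast_1d(np.asarray(alt_reads, dtype=np.int64))
    e = float(base_error)
    log_e, log_1e, log_h = np.log(e), np.log1p(-e), np.log(0.5)
    ll = np.stack(
        [
            a * log_e + r * log_1e,        # hom-ref
            (a + r) * log_h,               # het
            a * log_1e + r * log_e,        # hom-alt
        ]
    )
    # ties break toward fewer variant alleles: argmax on the first axis picks
    # the lowest genotype index at equal likelihood
    gt = ll.argmax(axis=0).astype(np.int8)
    gt[(gt > HOM_REF) & (a < min_alt_reads)] = HOM_REF
    gt[(r + a) == 0] = NO_CALL
    return gt.reshape(shape)


def genotype_site(
    column: PileupColumn,
    alt: int | None = None,
    min_alt_reads: int = 2,
    base_error: float = 0.005,
) -> GenotypeCall:
    """Genotype one pileup column.

    ``alt`` designates the alternate allele (e.g. the array's B allele in a
    concordance run); when None the most frequent non-reference base is used.
    """
    totals = column.counts[:, :, :4].sum(axis=(0, 1))
    depth = int(column.counts[:, :, :5].sum())
    ref_reads = int(totals[column.ref])
    if alt is None:
        masked = totals.copy()
        masked[column.ref] = 0
        alt = int(masked.argmax()) if masked.sum() else (column.ref + 1) % 4
    alt_reads = int(totals[alt])
    gt = int(genotype_counts(np.array(ref_reads), np.array(alt_reads), min_alt_reads, base_error))
    informative = ref_reads + alt_reads
    frac = alt_reads / informative if informative else 0.0
    return GenotypeCall(
        ref_id=column.ref_id,
        pos=column.pos,
        genotype=gt,
        depth=depth,
        alt_fraction=frac,
        ref_reads=ref_reads,
        alt_reads=alt_reads,
    )


def reclassify_counts(
    genotypes: np.ndarray,
    ref_reads: np.ndarray,
    alt_reads: np.ndarray,
    min_fraction: float = 0.20,
) -> np.ndarray:
    """Vectorized allelic-fraction reclassification of het calls.

    Hets with a reference-read fraction below ``min_fraction`` become hom-alt;
    hets with an alt-read fraction below it become hom-ref.  Idempotent, and
    non-het genotypes pass through untouched.
    """
    gt = np.asarray(genotypes).copy()
    r = np.asarray(ref_reads, dtype=np.float64)
    a = np.asarray(alt_reads, dtype=np.float64)
    tot = r + a
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_frac = np.where(tot > 0, r / tot, 0.0)
        alt_frac = np.where(tot > 0, a / tot, 0.0)
    is_het = gt == HET
    gt[is_het & (ref_frac < min_fraction)] = HOM_ALT
    gt[is_het & (alt_frac < min_fraction)] = HOM_REF
    return gt


def reclassify_allele_fraction(call: GenotypeCall, min_fraction: float = 0.20) -> GenotypeCall:
    """Apply the 20% allelic-fraction rule to a single call."""
    if call.genotype != HET:
        return call
    gt = int(
        reclassify_counts(
            np.array([call.genotype]),
            np.array([call.ref_reads]),
            np.array([call.alt_reads]),
            min_fraction,
        )[0]
    )
    return replace(call, genotype=gt)


def depth_filter(calls: list[GenotypeCall], max_depth: int = 1000) -> list[GenotypeCall]:
    """Flag calls whose site depth exceeds the cap (collapsed-repeat guard)."""
    return [replace(c, passed_filters=c.depth <= max_depth) for c in calls]
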