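"""Quantifying index misattribution (index switching) in multiplexed captures.

The estimator exploits array-validated positions with cohort minor allele
frequencies near 50% (39-59%): at such positions roughly half of all pool
reads carry the variant allele, so a read that lands on an individual who is
homozygous wild type by array and yet shows the variant allele is either a
sequencing/alignment artifact or a read wearing someone else's index.

Staged rates (all in percent of reads):

* ``observed``   r_obs - variant-read share among hom-WT individuals' reads
                 at mid-frequency positions;
* ``background`` b     - the same share at positions with zero cohort variant
                 alleles (pure error/artifact floor);
* ``seen``       s = max(r_obs - b, 0);
* ``total``      2s    - switching is random, so an index hopping between two
                 like-genotype reads is invisible; at 50% MAF exactly half of
                 switches are seen, hence the doubling;
* ``jumping_adjusted`` = total - j, discounting the expected jumping-PCR
                 contribution (0.7% by default) when requested.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import ArrayGenotypeTable
from .individual_caller import HOM_REF

DEFAULT_MAF_RANGE = (0.39, 0.59)
DEFAULT_JUMPING_PCR_PERCENT = 0.7


@dataclass
class AlleleCountBin:
    variant_alleles: int          # cohort variant-allele count from the array
    n_positions: int
    wt_reads: int                 # reads in hom-WT individuals matching WT
    variant_reads: int            # reads in hom-WT individuals showing the variant

    @property
    def total_reads(self) -> int:
        return self.wt_reads + self.variant_reads

    @property
    def rate_percent(self) -> float:
        t = self.total_reads
        return 100.0 * self.variant_reads / t if t else float("nan")


@dataclass
class MisattributionEstimate:
    observed_percent: float       # r_obs
    background_percent: float     # b
    jumping_percent: float

    @property
    def seen_percent(self) -> float:
        return max(self.observed_percent - self.background_percent, 0.0)

    @property
    def total_percent(self) -> float:
        return 2.0 * self.seen_percent

    @property
    def jumping_adjusted_percent(self) -> float:
        return self.total_percent - self.jumping_percent


def select_midfreq_positions(
    table: ArrayGenotypeTable,
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
    exclude_samples: list[str] | None = None,
) -> np.ndarray:
    """Mask of positions fully called across included samples with MAF in range.

    The cohort frequency is computed from included samples only, and the
    range check is inclusive at both ends.
    """
    keep = _sample_mask(table, exclude_samples)
    g = table.genotypes[:, keep]
    full = (g >= 0).all(axis=1)
    va = np.where(g > 0, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        maf = va / (2 * keep.sum())
    lo, hi = maf_range
    return full & (maf >= lo) & (maf <= hi)


def _sample_mask(table: ArrayGenotypeTable, exclude: list[str] | None) -> np.ndarray:
    excl = set(exclude or [])
    return np.array([s not in excl for s in table.samples])


def _binned_rates(
    wt_reads: np.ndarray,
    variant_reads: np.ndarray,
    table: ArrayGenotypeTable,
    positions_mask: np.ndarray,
    sample_keep: np.ndarray,
) -> list[AlleleCountBin]:
    g = table.genotypes[:, sample_keep]
    va = np.where(g > 0, g, 0).sum(axis=1)
    wt = wt_reads[:, sample_keep]
    var = variant_reads[:, sample_keep]
    hom_wt = g == HOM_REF
    bins: list[AlleleCountBin] = []
    for count in sorted(set(va[positions_mask])):
        rows = positions_mask & (va == count)
        cell = rows[:, None] & hom_wt
        bins.append(
            AlleleCountBin(
                variant_alleles=int(count),
                n_positions=int(rows.sum()),
                wt_reads=int(wt[cell].sum()),
                variant_reads=int(var[cell].sum()),
            )
        )
    return bins


def observed_misattribution(
    wt_reads: np.ndarray,
    variant_reads: np.ndarray,
    table: ArrayGenotypeTable,
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
    exclude_samples: list[str] | None = None,
) -> tuple[list[AlleleCountBin], float, float]:
    """Variant-read rates among hom-WT individuals at mid-frequency positions.

    ``wt_reads``/``variant_reads`` are (positions, samples) read-count
    matrices.  Returns the per-allele-count bins, the read-weighted aggregate
    rate r_obs (%), and the per-sample average rate (%) — the two natural
    aggregations of the same counts.
    """
    keep = _sample_mask(table, exclude_samples)
    mask = select_midfreq_positions(table, maf_range, exclude_samples)
    bins = _binned_rates(wt_reads, variant_reads, table, mask, keep)
    tot_var = sum(b.variant_reads for b in bins)
    tot = sum(b.total_reads for b in bins)
    r_obs = 100.0 * tot_var / tot if tot else float("nan")

    g = table.genotypes[:, keep]
    hom_wt = (g == HOM_REF) & mask[:, None]
    wt = np.where(hom_wt, wt_reads[:, keep], 0).sum(axis=0)
    var = np.where(hom_wt, variant_reads[:, keep], 0).sum(axis=0)
    denom = wt + var
    with np.errstate(invalid="ignore"):
        per_sample = np.where(denom > 0, 100.0 * var / denom, np.nan)
    sample_avg = float(np.nanmean(per_sample)) if np.isfinite(per_sample).any() else float("nan")
    return bins, r_obs, sample_avg


def background_rate(
    wt_reads: np.ndarray,
    variant_reads: np.ndarray,
    table: ArrayGenotypeTable,
    exclude_samples: list[str] | None = None,
) -> float:
    """Variant-read percentage at positions with zero cohort variant alleles.

    Attributable to sequencing error or alignment artifacts rather than index
    switching, and subtracted from the observed mid-frequency rate.
    """
    keep = _sample_mask(table, exclude_samples)
    g = table.genotypes[:, keep]
    full = (g >= 0).all(axis=1)
    va = np.where(g > 0, g, 0).sum(axis=1)
    zero = full & (va == 0)
    if not zero.any():
        raise ValueError("no fully-called positions with zero variant alleles")
    wt = wt_reads[np.ix_(zero, keep)].sum()
    var = variant_reads[np.ix_(zero, keep)].sum()
    total = wt + var
    if total == 0:
        raise ValueError("no reads at zero-variant positions")
    return float(100.0 * var / total)


def estimate_switching(
    observed_percent: float,
    background_percent: float,
    jumping_percent: float = DEFAULT_JUMPING_PCR_PERCENT,
) -> MisattributionEstimate:
    """Staged misattribution estimate from the observed and background rates."""
    if observed_percent < 0 or background_percent < 0:
        raise ValueError("rates must be non-negative")
    return MisattributionEstimate(
        observed_percent=float(observed_percent),
        background_percent=float(background_percent),
        jumping_percent=float(jumping_percent),
    )


def estimate_to_frame(est: MisattributionEstimate, bins: list[AlleleCountBin] | None = None):
    rows = [
        ("observed_%", est.observed_percent),
        ("background_%", est.background_percent),
        ("seen_%", est.seen_percent),
        ("total_%", est.total_percent),
        ("jumping_adjusted_%", est.jumping_adjusted_percent),
    ]
    frames = {"estimate": pd.DataFrame(rows, columns=["stage", "percent"])}
    if bins is not None:
        frames["bins"] = pd.DataFrame(
            [
                {
                    "variant_alleles": b.variant_alleles,
                    "positions": b.n_positions,
                    "wt_reads": b.wt_reads,
                    "variant_reads": b.variant_reads,
                    "rate_%": b.rate_percent,
                }
                for b in bins
            ]
        )
    return frames
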