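"""Synthetic cohorts, capture reads and sequencing controls.

This module emulates the data-generating process behind pooled and indexed
hybridization-capture experiments well enough to exercise every downstream
stage offline:

* diploid cohorts with variants planted at exact pool allele counts,
* paired-end reads with an in-line 7 bp sample index at the 3' end of read 1,
* per-cycle substitution errors with optional elevated (aberrant) cycles,
* exact-copy PCR duplicates and index switching at configurable rates,
* variant-free control reads for error-model calibration.

Defaults mirror the headline experimental design this package analyses:
101 bp paired reads, 7 bp indexes, 92-individual cohorts, ~13% duplication,
~3.4% index switching, mean target coverage ~30x.

Because every read carries provenance (true sample, coordinates, duplicate
and switched-index flags), parameter-recovery tests can compare any pipeline
output against the exact truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reads import AlignedReadSet
from .seq import GAP_CODE, decode, random_sequence

DEFAULT_SEED = 1729


@dataclass
class Variant:
    """A planted variant: 1-based position, ref/alt labels, pool allele count."""

    pos: int           # 1-based reference position
    ref: str
    alt: str           # single base for SNV; "+X" 1bp insertion; "-" 1bp deletion
    count: int         # variant allele count in the pool (k)

    @property
    def kind(self) -> str:
        if self.alt.startswith("+"):
            return "INS1"
        if self.alt == "-":
            return "DEL1"
        return "SNV"


@dataclass
class SimConfig:
    seed: int = DEFAULT_SEED
    reference_length: int = 10_000
    n_individuals: int = 92
    read_length: int = 101            # read 1 = (read_length - index_length) genomic + index
    index_length: int = 7
    variant_spec: list[Variant] = field(default_factory=list)
    per_cycle_error: float | np.ndarray = 0.002   # substitution prob per base per cycle
    elevated_cycles: list[tuple[int, float]] = field(default_factory=list)
    duplication_rate: float = 0.134
    switching_rate: float = 0.034
    mean_depth: float = 30.0          # mean read depth per individual per site
    fragment_mean: int = 280
    fragment_sd: int = 100
    index_at_5prime: bool = False     # default in-line index sits at the 3' end of read 1

    def validate(self) -> None:
        if self.read_length <= self.index_length:
            raise ValueError("read_length must exceed index_length")
        rates = [self.duplication_rate, self.switching_rate]
        rates += [r for _, r in self.elevated_cycles]
        rates += list(np.atleast_1d(self.per_cycle_error))
        if any(not (0.0 <= float(r) <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        two_n = 2 * self.n_individuals
        for v in self.variant_spec:
            if v.count > two_n:
                raise ValueError(
                    f"variant at {v.pos}: allele count {v.count} exceeds pool size {two_n}"
                )
            if not (1 <= v.pos <= self.reference_length):
                raise ValueError(f"variant position {v.pos} outside reference")

    def cycle_error_profile(self, n_cycles: int) -> np.ndarray:
        prof = np.broadcast_to(
            np.atleast_1d(np.asarray(self.per_cycle_error, dtype=float)), (n_cycles,)
        ).copy()
        for cycle, rate in self.elevated_cycles:
            if not (1 <= cycle <= n_cycles):
                raise ValueError(f"elevated cycle {cycle} outside 1..{n_cycles}")
            prof[cycle - 1] = rate
        return prof


@dataclass
class CohortTruth:
    """Planted genotypes plus haplotype phase for a simulated cohort."""

    config: SimConfig
    reference: np.ndarray              # (R,) uint8
    variants: list[Variant]
    genotypes: np.ndarray              # (n_sites, n_individuals) int8 in {0,1,2}
    hap_alt: np.ndarray                # (n_sites, n_individuals, 2) bool: haplotype carries alt

    @property
    def pool_allele_counts(self) -> np.ndarray:
        return self.genotypes.sum(axis=1)

    @property
    def pool_mafs(self) -> np.ndarray:
        return self.pool_allele_counts / (2 * self.config.n_individuals)


def simulate_cohort(config: SimConfig) -> CohortTruth:
    """Draw a cohort whose variant allele counts match the request *exactly*.

    For each site, ``k`` of the ``2N`` chromosomes are chosen without
    replacement to carry the alternate allele, so the pool allele count is k
    by construction rather than in expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    reference = random_sequence(config.reference_length, rng)
    n = config.n_individuals
    n_sites = len(config.variant_spec)
    genotypes = np.zeros((n_sites, n), dtype=np.int8)
    hap_alt = np.zeros((n_sites, n, 2), dtype=bool)
    for s, v in enumerate(config.variant_spec):
        # pin the reference base under the variant to its declared ref allele
        if v.ref in "ACGT":
            reference[v.pos - 1] = "ACGT".index(v.ref)
        chroms = rng.choice(2 * n, size=v.count, replace=False)
        hap_alt[s, chroms // 2, chroms % 2] = True
        genotypes[s] = hap_alt[s].sum(axis=1)
    return CohortTruth(config, reference, list(config.variant_spec), genotypes, hap_alt)


@dataclass
class SimulatedReads:
    """Paired reads plus full per-read provenance and a truth alignment."""

    config: SimConfig
    r1: np.ndarray                     # (n, read_length) uint8, sequencing orientation
    r2: np.ndarray                     # (n, genomic_length) uint8, sequencing orientation
    index_codes: list[str]             # per-sample 7 bp codes, order = sample id
    read_index: np.ndarray             # (n,) sample whose code is on the read (post switching)
    true_sample: np.ndarray            # (n,) sample the DNA came from
    switched: np.ndarray               # (n,) bool
    duplicate: np.ndarray              # (n,) bool
    truth: AlignedReadSet              # 2n rows: genomic part of r1 then r2, correct coords

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def r1_index_matrix(self) -> np.ndarray:
        k = self.config.index_length
        return self.r1[:, :k] if self.config.index_at_5prime else self.r1[:, -k:]

    def write_fastq(self, r1_path: str, r2_path: str) -> None:
        qual1 = "?" * self.r1.shape[1]  # fixed Q30 placeholder
        qual2 = "?" * self.r2.shape[1]
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for i in range(self.n_pairs):
                f1.write(f"@pair{i}/1\n{decode(self.r1[i])}\n+\n{qual1}\n")
                f2.write(f"@pair{i}/2\n{decode(self.r2[i])}\n+\n{qual2}\n")


def _apply_cycle_errors(
    seq_aligned: np.ndarray, strands: np.ndarray, profile: np.ndarray, rng: np.random.Generator
) -> None:
    """Mutate aligned rows in place with per-cycle substitution errors.

    ``seq_aligned`` rows are reference-oriented; the error process operates in
    cycle space, so the per-cycle rate is applied at offset ``c-1`` for forward
    reads and ``L-c`` for reverse reads.
    """
    n, L = seq_aligned.shape
    fwd = np.flatnonzero(strands == 0)
    rev = np.flatnonzero(strands == 1)
    for cycle in range(1, L + 1):
        rate = profile[cycle - 1]
        if rate <= 0:
            continue
        for rows, off in ((fwd, cycle - 1), (rev, L - cycle)):
            if rows.size == 0:
                continue
            hit = rows[rng.random(rows.size) < rate]
            if hit.size == 0:
                continue
            cur = seq_aligned[hit, off]
            shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
            new = (cur + shift) % 4
            keep_gap = cur == GAP_CODE  # never mutate a deletion gap
            seq_aligned[hit, off] = np.where(keep_gap, cur, new)


def _default_index_codes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    from .demux import generate_index_codes

    return generate_index_codes(n, length=length, min_distance=2, rng=rng)


def simulate_reads(
    truth: CohortTruth, config: SimConfig | None = None, index_codes: list[str] | None = None
) -> SimulatedReads:
    """Emit indexed paired-end capture reads for a simulated cohort.

    Fragments start uniformly on the reference with length ~ N(280, 100)
    (clipped to hold both mates); read 1 carries the sample's index at its
    3' end.  Sequencing errors, exact-copy duplicates and index switching are
    applied per the config, and every read's provenance is retained.
    """
    config = config or truth.config
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    ref = truth.reference
    R = len(ref)
    n_ind = config.n_individuals
    g1 = config.read_length - config.index_length   # genomic span of read 1
    g2 = config.read_length                         # read 2 is fully genomic
    gmax = max(g1, g2)

    if index_codes is None:
        index_codes = _default_index_codes(n_ind, config.index_length, rng)
    if len(index_codes) < n_ind:
        raise ValueError("need at least one index code per individual")

    pairs_per_ind = max(1, int(round(config.mean_depth * R / (g1 + g2))))
    n_pairs = pairs_per_ind * n_ind
    sample = np.repeat(np.arange(n_ind), pairs_per_ind)

    frag_len = np.clip(
        np.rint(rng.normal(config.fragment_mean, config.fragment_sd, n_pairs)).astype(np.int64),
        gmax,
        R,
    )
    frag_start = (rng.random(n_pairs) * (R - frag_len + 1)).astype(np.int64)
    frag_strand = rng.integers(0, 2, n_pairs, dtype=np.uint8)  # 0: r1 at left end
    hap = rng.integers(0, 2, n_pairs, dtype=np.uint8)

    # mate coordinates in reference space; r1 reads the fragment 5' end
    r1_start = np.where(frag_strand == 0, frag_start, frag_start + frag_len - g1)
    r1_strand = frag_strand
    r2_start = np.where(frag_strand == 0, frag_start + frag_len - g2, frag_start)
    r2_strand = 1 - frag_strand

    offs1 = np.arange(g1)
    offs2 = np.arange(g2)
    aln1 = ref[r1_start[:, None] + offs1].copy()
    aln2 = ref[r2_start[:, None] + offs2].copy()

    # (mate 0/1, pair index, ref_offset, base); materialized to truth rows later
    ins_events: list[tuple[int, int, int, int]] = []
    for s, v in enumerate(truth.variants):
        carrier = truth.hap_alt[s, sample, hap]
        p0 = v.pos - 1
        for mate, (aln, starts) in enumerate(((aln1, r1_start), (aln2, r2_start))):
            width = aln.shape[1]
            off = p0 - starts
            cov = carrier & (off >= 0) & (off < width)
            idx = np.flatnonzero(cov)
            if idx.size == 0:
                continue
            if v.kind == "SNV":
                aln[idx, off[idx]] = "ACGT".index(v.alt)
            elif v.kind == "DEL1":
                aln[idx, off[idx]] = GAP_CODE
            else:  # INS1 after pos
                base = "ACGT".index(v.alt[1])
                ins_events.extend((mate, int(i), int(off[i]), base) for i in idx)

    profile1 = config.cycle_error_profile(g1)
    profile2 = config.cycle_error_profile(g2)
    _apply_cycle_errors(aln1, r1_strand, profile1, rng)
    _apply_cycle_errors(aln2, r2_strand, profile2, rng)

    # duplicates: exact copies of existing pairs, appended and flagged
    n_dup = int(round(config.duplication_rate / (1 - config.duplication_rate) * n_pairs)) if config.duplication_rate else 0
    if n_dup:
        src = rng.integers(0, n_pairs, n_dup)
        aln1 = np.vstack([aln1, aln1[src]])
        aln2 = np.vstack([aln2, aln2[src]])
        by_pair: dict[int, list[tuple[int, int, int, int]]] = {}
        for ev in ins_events:
            by_pair.setdefault(ev[1], []).append(ev)
        for i, s_ in enumerate(src):
            for mate, _, off, b in by_pair.get(int(s_), []):
                ins_events.append((mate, n_pairs + i, off, b))
        r1_start = np.concatenate([r1_start, r1_start[src]])
        r1_strand = np.concatenate([r1_strand, r1_strand[src]])
        r2_start = np.concatenate([r2_start, r2_start[src]])
        r2_strand = np.concatenate([r2_strand, r2_strand[src]])
        sample = np.concatenate([sample, sample[src]])
        n_total = n_pairs + n_dup
    else:
        n_total = n_pairs
    duplicate = np.zeros(n_total, dtype=bool)
    duplicate[n_pairs:] = True

    # index switching: the pair carries another sample's code
    switched = rng.random(n_total) < config.switching_rate
    read_index = sample.copy()
    if switched.any():
        k = int(switched.sum())
        shift = rng.integers(1, n_ind, k)
        read_index[switched] = (sample[switched] + shift) % n_ind

    # index bases, with the same per-cycle error applied at their cycles
    code_mat = np.vstack([np.frombuffer(c.encode(), dtype=np.uint8) for c in index_codes])
    from .seq import _ENCODE  # encoded code matrix

    code_mat = _ENCODE[code_mat]
    idx_bases = code_mat[read_index].copy()
    idx_cycles = (
        np.arange(config.index_length)
        if config.index_at_5prime
        else g1 + np.arange(config.index_length)
    )
    full_profile = config.cycle_error_profile(config.read_length)
    for j, cyc in enumerate(idx_cycles):
        rate = full_profile[cyc]
        hit = np.flatnonzero(rng.random(n_total) < rate)
        if hit.size:
            idx_bases[hit, j] = (idx_bases[hit, j] + rng.integers(1, 4, hit.size, dtype=np.uint8)) % 4

    # sequencing-orientation FASTQ matrices (reverse-strand rows revcomp'ed);
    # deletion gaps are dropped per read, padding with the next reference base
    r1_seqread = _to_sequencing_orientation(aln1, r1_strand, r1_start, ref)
    r2_seqread = _to_sequencing_orientation(aln2, r2_strand, r2_start, ref)
    if config.index_at_5prime:
        r1 = np.hstack([idx_bases, r1_seqread])
    else:
        r1 = np.hstack([r1_seqread, idx_bases])

    row_events = [
        (pair if mate == 0 else n_total + pair, off, b) for mate, pair, off, b in ins_events
    ]
    truth_set = _stacked_truth(
        ref, aln1, r1_start, r1_strand, aln2, r2_start, r2_strand, row_events, duplicate
    )

    return SimulatedReads(
        config=config,
        r1=r1,
        r2=r2_seqread,
        index_codes=list(index_codes),
        read_index=read_index,
        true_sample=sample,
        switched=switched,
        duplicate=duplicate,
        truth=truth_set,
    )


def _to_sequencing_orientation(
    aln: np.ndarray, strand: np.ndarray, start: np.ndarray, ref: np.ndarray
) -> np.ndarray:
    """Convert reference-oriented aligned rows to as-sequenced base calls."""
    from .seq import complement

    out = aln.copy()
    rev = np.flatnonzero(strand == 1)
    if rev.size:
        out[rev] = complement(aln[rev])[:, ::-1]
    gap_rows = np.flatnonzero((out == GAP_CODE).any(axis=1))
    for i in gap_rows:
        row = out[i]
        kept = row[row != GAP_CODE]
        pad_pos = start[i] + aln.shape[1]
        pad = ref[pad_pos] if pad_pos < len(ref) else 0
        out[i] = np.concatenate([kept, np.full(len(row) - len(kept), pad, np.uint8)])
    return out


def _stacked_truth(ref, aln1, s1, st1, aln2, s2, st2, ins_events, duplicate) -> AlignedReadSet:
    g1, g2 = aln1.shape[1], aln2.shape[1]
    n = aln1.shape[0]
    if g1 == g2:
        seq = np.vstack([aln1, aln2])
        start = np.concatenate([s1, s2])
        strand = np.concatenate([st1, st2]).astype(np.uint8)
        names = [f"pair{i}/1" for i in range(n)] + [f"pair{i}/2" for i in range(n)]
        dup = np.concatenate([duplicate, duplicate])
        ins = np.array(ins_events, dtype=np.int64) if ins_events else np.empty((0, 3), np.int64)
        return AlignedReadSet(
            ref_name="ref1", ref=ref, seq=seq, start=start, strand=strand,
            names=names, insertions=ins, duplicate=dup,
        )
    # mates of unequal genomic span: keep read 2 only rows padded? store mates
    # separately by truncating the longer mate to the common span for pileup use
    g = min(g1, g2)
    seq = np.vstack([aln1[:, :g], aln2[:, :g]])
    start = np.concatenate([s1, s2])
    strand = np.concatenate([st1, st2]).astype(np.uint8)
    names = [f"pair{i}/1" for i in range(n)] + [f"pair{i}/2" for i in range(n)]
    dup = np.concatenate([duplicate, duplicate])
    ins = np.array([e for e in ins_events if e[1] < g], dtype=np.int64) if ins_events else np.empty((0, 3), np.int64)
    return AlignedReadSet(
        ref_name="ref1", ref=ref, seq=seq, start=start, strand=strand,
        names=names, insertions=ins, duplicate=dup,
    )


def simulate_control_reads(
    control_reference: np.ndarray,
    error_profile: float | np.ndarray,
    n_reads: int,
    seed: int,
    read_length: int = 80,
    elevated_cycles: list[tuple[int, float]] | None = None,
    indel_rate: float = 0.0,
) -> AlignedReadSet:
    """Variant-free control reads for calibrating the sequencing error model.

    Reads are drawn uniformly from both strands of the control reference
    (a PhiX174-like negative control) with the configured per-cycle
    substitution profile.  ``indel_rate`` plants rare 1 bp deletion errors so
    the indel arm of the error model has observations to estimate from.
    """
    ref = np.asarray(control_reference, dtype=np.uint8)
    if ref.size == 0:
        raise ValueError("control reference is empty")
    if ref.size < read_length:
        raise ValueError("control reference shorter than read length")
    rng = np.random.default_rng(seed)
    L = read_length
    profile = np.broadcast_to(np.atleast_1d(np.asarray(error_profile, float)), (L,)).copy()
    for cycle, rate in elevated_cycles or []:
        profile[cycle - 1] = rate

    start = rng.integers(1, ref.size - L + 1, n_reads)  # start>=1 keeps a context base
    strand = rng.integers(0, 2, n_reads, dtype=np.uint8)
    seq = np.empty((n_reads, L), dtype=np.uint8)
    offs = np.arange(L)
    for lo in range(0, n_reads, 100_000):
        hi = min(lo + 100_000, n_reads)
        seq[lo:hi] = ref[start[lo:hi, None] + offs]
    _apply_cycle_errors(seq, strand, profile, rng)
    if indel_rate > 0:
        hits = np.flatnonzero(rng.random(n_reads) < indel_rate)
        if hits.size:
            seq[hits, rng.integers(0, L, hits.size)] = GAP_CODE
    names = None  # keep memory down for large control sets
    return AlignedReadSet(
        ref_name="control", ref=ref, seq=seq, start=start, strand=strand, names=names
    )


def simulate_genotype_observations(
    n_sites: int,
    n_individuals: int,
    alleles_per_site: int,
    mean_depth_per_chr: float,
    base_error: float,
    seed: int,
):
    """Column-level cohort simulation for genotype concordance experiments.

    Draws, for every (site, individual) cell, a Poisson read depth (mean =
    2 x per-chromosome coverage) and the reads observed as the designated
    alternate allele / reference / any other base, given the individual's true
    genotype and a per-base substitution error that lands uniformly on the
    three non-template bases.  Returns a dict of (n_sites, n_individuals)
    arrays: ``depth``, ``alt``, ``ref``, ``truth`` (genotype 0/1/2).
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        reference_length=max(n_sites * 2, 100),
        n_individuals=n_individuals,
        variant_spec=[
            Variant(pos=2 * s + 1, ref="A", alt="C", count=alleles_per_site)
            for s in range(n_sites)
        ],
        mean_depth=2 * mean_depth_per_chr,
    )
    truth = simulate_cohort(cfg)
    g = truth.genotypes.astype(np.int64)

    depth = rng.poisson(2.0 * mean_depth_per_chr, size=g.shape)
    true_alt = rng.binomial(depth, g / 2.0)
    true_ref = depth - true_alt
    e = float(base_error)
    alt_kept = rng.binomial(true_alt, 1.0 - e)
    alt_to_ref = rng.binomial(true_alt - alt_kept, 1.0 / 3.0)
    ref_kept = rng.binomial(true_ref, 1.0 - e)
    ref_to_alt = rng.binomial(true_ref - ref_kept, 1.0 / 3.0)
    obs_alt = alt_kept + ref_to_alt
    obs_ref = ref_kept + alt_to_ref
    return {
        "depth": depth,
        "alt": obs_alt,
        "ref": obs_ref,
        "truth": truth.genotypes,
        "pool_allele_count": truth.pool_allele_counts,
    }
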