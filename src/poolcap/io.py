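"""File-format readers/writers, run configuration and the two pipelines.

Coordinate conventions: BED input is 0-based half-open and is converted on
read to the package-internal 1-based inclusive intervals; all positions in
reports are 1-based.  FASTA parsing goes through Biopython, SAM through
pysam; FASTQ uses a small streaming reader so multi-gigabyte lanes never
materialize in memory.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import concordance as conc
from . import contamination as contam
from .capture_metrics import compute_metrics
from .concordance import ArrayGenotypeTable
from .demux import IndexSet, demultiplex, validate_index_set
from .error_model import ErrorModel, build_error_model
from .individual_caller import genotype_site, reclassify_allele_fraction
from .pool_caller import (
    PoolCallerParams,
    build_pileup,
    call_pool_indels_1bp,
    call_pool_variants,
    calls_to_frame,
    trim_reads,
)
from .reads import AlignedReadSet
from .seq import decode, encode

logger = logging.getLogger("poolcap")


# ------------------------------------------------------------------- formats

def read_fasta(path: str) -> dict[str, np.ndarray]:
    """FASTA file to {name: uint8 base codes}."""
    out = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = encode(str(rec.seq).upper())
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def write_fasta(path: str, seqs: dict[str, np.ndarray]) -> None:
    with open(path, "w") as f:
        for name, codes in seqs.items():
            s = decode(np.asarray(codes, dtype=np.uint8))
            f.write(f">{name}\n")
            for i in range(0, len(s), 70):
                f.write(s[i : i + 70] + "\n")


def read_fastq(path: str) -> Iterator[tuple[str, str, str]]:
    """Stream (name, sequence, quality) records; validates record structure."""
    with open(path) as f:
        rec = 0
        while True:
            header = f.readline()
            if not header:
                return
            seq = f.readline()
            plus = f.readline()
            qual = f.readline()
            rec += 1
            if not qual or not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"truncated or malformed FASTQ record {rec} in {path}")
            seq, qual = seq.strip(), qual.strip()
            if len(seq) != len(qual):
                raise ValueError(f"sequence/quality length mismatch at record {rec} in {path}")
            yield header[1:].strip().split()[0], seq, qual


def read_fastq_pairs(r1_path: str, r2_path: str):
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    for rec1 in it1:
        try:
            rec2 = next(it2)
        except StopIteration:
            raise ValueError(f"{r2_path} has fewer records than {r1_path}") from None
        yield rec1, rec2


def write_fastq(path: str, records: list[tuple[str, str, str]]) -> None:
    with open(path, "w") as f:
        for name, seq, qual in records:
            f.write(f"@{name}\n{seq}\n+\n{qual}\n")


def fastq_to_matrix(path: str) -> tuple[list[str], np.ndarray]:
    """Load a uniform-length FASTQ into (names, base-code matrix)."""
    names, rows = [], []
    for name, seq, _ in read_fastq(path):
        names.append(name)
        rows.append(encode(seq))
    if not rows:
        raise ValueError(f"no records in {path}")
    return names, np.vstack(rows)


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """BED (0-based half-open) -> list of (chrom, start, end) 1-based inclusive."""
    out = []
    with open(path) as f:
        for ln, line in enumerate(f, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln} in {path}")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            out.append((chrom, start0 + 1, end0))
    return out


def write_bed(path: str, intervals: list[tuple[str, int, int]]) -> None:
    """Internal 1-based inclusive intervals -> BED 0-based half-open."""
    with open(path, "w") as f:
        for chrom, start1, end1 in intervals:
            f.write(f"{chrom}\t{start1 - 1}\t{end1}\n")


def read_sam(path: str, ref: np.ndarray, ref_name: str | None = None) -> AlignedReadSet:
    return AlignedReadSet.from_sam(path, ref, ref_name)


def read_genotype_table(path: str) -> ArrayGenotypeTable:
    return ArrayGenotypeTable.from_tsv(path)


def read_index_tsv(path: str) -> IndexSet:
    """One code per line (optionally 'sample<TAB>code'); validated on load."""
    codes = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codes.append(line.split("\t")[-1].split()[-1])
    return validate_index_set(codes)


# -------------------------------------------------------------- run pipeline

_RUN_FIELDS = {
    "mode", "seed", "reference", "targets", "sam", "r1", "r2", "indexes",
    "control_sam", "model", "array_table", "outdir", "two_n", "cutoff",
    "trim_length", "cycle_threshold", "error_model_order", "min_alt_reads",
    "base_error", "reclassify_fraction", "max_depth", "log_level",
}


@dataclass
class RunConfig:
    mode: str = "pooled"              # pooled | indexed
    seed: int = 1729
    reference: str = ""
    targets: str = ""
    sam: str = ""
    r1: str = ""
    r2: str = ""
    indexes: str = ""
    control_sam: str = ""
    model: str = ""
    array_table: str = ""
    outdir: str = "poolcap_out"
    two_n: int = 200
    cutoff: float = -1.3
    trim_length: int = 80
    cycle_threshold: float = 0.0002
    error_model_order: int = 2
    min_alt_reads: int = 2
    base_error: float = 0.005
    reclassify_fraction: float = 0.20
    max_depth: int = 1000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        unknown = set(raw) - _RUN_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump({fld.name: getattr(self, fld.name) for fld in fields(self)}, f)


def _stage(name: str, n_in: int, n_out: int) -> None:
    logger.info("stage=%s in=%d out=%d", name, n_in, n_out)


def run_pipeline(config: RunConfig) -> dict:
    """Run the pooled or indexed pipeline end to end; returns a report bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    required = {"pooled": ["reference", "sam", "targets"],
                "indexed": ["reference", "r1", "r2", "indexes", "sam", "targets"]}
    if config.mode not in required:
        raise ValueError(f"unknown mode {config.mode!r}")
    missing = [k for k in required[config.mode] if not getattr(config, k)]
    missing += [
        k for k in required[config.mode] + ["control_sam", "model", "array_table"]
        if getattr(config, k) and not Path(getattr(config, k)).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    outdir.mkdir(parents=True, exist_ok=True)
    refs = read_fasta(config.reference)
    ref_name, ref = next(iter(refs.items()))
    targets = [(s, e) for _, s, e in read_bed(config.targets)]
    if config.mode == "pooled":
        return _run_pooled(config, ref_name, ref, targets, outdir)
    return _run_indexed(config, ref_name, ref, targets, outdir)


def _load_model(config: RunConfig, ref: np.ndarray) -> ErrorModel:
    if config.model:
        return ErrorModel.from_tsv(config.model)
    if not config.control_sam:
        raise FileNotFoundError("need either a model TSV or a control SAM")
    control = read_sam(config.control_sam, ref)
    model = build_error_model(control, order=config.error_model_order)
    model.excluded_cycles(config.cycle_threshold)
    return model


def _run_pooled(config, ref_name, ref, targets, outdir: Path) -> dict:
    reads = read_sam(config.sam, ref, ref_name)
    model = _load_model(config, ref)
    trimmed = trim_reads(reads, config.trim_length)
    unique, mult = trimmed.unique()
    _stage("compress", trimmed.n_reads, unique.n_reads)
    mm_ok = unique.mismatch_counts() <= 5
    unique = unique.subset(np.flatnonzero(mm_ok))
    pileup = build_pileup(unique, targets, excluded_cycles=model.excluded)
    _stage("pileup", unique.n_reads, len(pileup))
    params = PoolCallerParams(cutoff=config.cutoff, two_n=config.two_n,
                              trim_length=config.trim_length)
    calls, coverage = call_pool_variants(pileup, model, params)
    indels = call_pool_indels_1bp(pileup, model, params)
    _stage("poolcall", len(pileup), len(calls) + len(indels))
    calls_df = calls_to_frame(calls + indels)
    calls_df.to_csv(outdir / "pool_calls.tsv", sep="\t", index=False)
    coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    report = {"calls": calls_df, "coverage": coverage}
    if config.array_table:
        table = read_genotype_table(config.array_table)
        maf_by_pos = dict(zip(calls_df["pos"], calls_df["maf"]))
        pool_mafs = np.array([maf_by_pos.get(p, 0.0) for p in table.positions["pos"]])
        report["maf_concordance"] = conc.pooled_maf_concordance(pool_mafs, table.mafs())
    else:
        logger.info("no array table supplied; concordance stage skipped")
    return report


def _run_indexed(config, ref_name, ref, targets, outdir: Path) -> dict:
    index_set = read_index_tsv(config.indexes)
    names, r1 = fastq_to_matrix(config.r1)
    assignment, _, demux_result = demultiplex(r1, index_set)
    _stage("demux", len(names), int(demux_result.counts.sum()))
    demux_result.to_frame().to_csv(outdir / "demux_report.tsv", sep="\t", index=False)

    aligned = read_sam(config.sam, ref, ref_name)
    # map aligned records to pairs by their 'pair{i}/{mate}' names
    pair_of = np.array([int(n.split("/")[0].removeprefix("pair")) for n in aligned.names])
    read_sample = assignment[pair_of]
    model_excluded: set[int] = set()

    table = read_genotype_table(config.array_table) if config.array_table else None
    table_pos = {}
    if table is not None:
        from .seq import BASES

        table_pos = {
            int(p): (BASES.index(r) if r in BASES else None,
                     BASES.index(a) if a in BASES else None)
            for p, r, a in zip(table.positions["pos"], table.positions["ref"],
                               table.positions["alt"])
        }
        n_pos = table.n_positions
        called_geno = np.full((n_pos, len(index_set.codes)), -1, dtype=np.int8)
        wt_reads = np.zeros((n_pos, len(index_set.codes)), dtype=np.int64)
        var_reads = np.zeros_like(wt_reads)
        row_of = {int(p): i for i, p in enumerate(table.positions["pos"])}
    call_rows = []
    sample_metrics = []
    for j, code in enumerate(index_set.codes):
        sel = np.flatnonzero(read_sample == j)
        if sel.size == 0:
            continue
        sub = aligned.subset(sel)
        dup = sub.mark_duplicates()
        kept = sub.subset(np.flatnonzero(~dup))
        _stage(f"dedup[{code}]", sub.n_reads, kept.n_reads)
        metrics = compute_metrics(kept, targets, genome_size=len(ref), total_reads=sub.n_reads)
        sample_metrics.append({"sample": code, **{
            r.metric: r.value for r in metrics.to_frame().itertuples(index=False)}})
        pileup = build_pileup(kept, targets, excluded_cycles=model_excluded, flank=50)
        for col in pileup:
            alt = None
            if col.pos in table_pos:
                _, alt = table_pos[col.pos]
            call = genotype_site(col, alt=alt, min_alt_reads=config.min_alt_reads,
                                 base_error=config.base_error)
            call = reclassify_allele_fraction(call, config.reclassify_fraction)
            call_rows.append({"sample": code, "ref_id": col.ref_id, "pos": col.pos,
                              "genotype": call.genotype_name, "depth": call.depth,
                              "alt_fraction": call.alt_fraction,
                              "genotype_code": call.genotype})
            if table is not None and col.pos in row_of:
                i = row_of[col.pos]
                called_geno[i, j] = call.genotype
                wt_reads[i, j] = call.ref_reads
                var_reads[i, j] = call.alt_reads
    calls_df = pd.DataFrame(call_rows)
    if not calls_df.empty:
        calls_df["passed_filters"] = calls_df["depth"] <= config.max_depth
    calls_df.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    metrics_df = pd.DataFrame(sample_metrics)
    metrics_df.to_csv(outdir / "capture_metrics.tsv", sep="\t", index=False)
    report = {"demux": demux_result, "genotypes": calls_df, "metrics": metrics_df}
    if table is None:
        logger.info("no array table supplied; concordance and contamination skipped")
        return report
    # concordance requires the table's sample columns to be index codes
    if list(table.samples) == list(index_set.codes):
        res = conc.sensitivity_specificity(table.genotypes, called_geno)
        pd.DataFrame([res]).to_csv(outdir / "concordance.tsv", sep="\t", index=False)
        report["concordance"] = res
        try:
            bins, r_obs, sample_avg = contam.observed_misattribution(
                wt_reads, var_reads, table
            )
            b = contam.background_rate(wt_reads, var_reads, table)
            est = contam.estimate_switching(r_obs, b)
            frames = contam.estimate_to_frame(est, bins)
            frames["estimate"].to_csv(outdir / "contamination.tsv", sep="\t", index=False)
            report["contamination"] = est
        except ValueError as exc:
            logger.info("contamination stage skipped: %s", exc)
    else:
        logger.info("array table samples do not match index codes; concordance skipped")
    return report
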