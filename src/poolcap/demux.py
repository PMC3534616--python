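"""Index (barcode) validation and read demultiplexing.

Samples are tagged with fixed-length in-line indexes (7 bp by default) placed
at the 3' end of read 1.  A code set is only usable when every pair of codes
is at Hamming distance >= 2: a single sequencing error then lands a read at
distance 1 from its true code and at distance >= 1 from every other code, so
assignment with one allowed mismatch can correct any single error without
ever crossing to a different sample.  Equal-distance ties are deliberately
left unassigned (safety over yield).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .seq import decode, encode

UNASSIGNED = -1


class IndexValidationError(ValueError):
    pass


@dataclass(frozen=True)
class IndexSet:
    codes: tuple[str, ...]
    index_length: int
    min_pairwise_hamming: int

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def matrix(self) -> np.ndarray:
        return np.vstack([encode(c) for c in self.codes])


@dataclass
class DemuxResult:
    codes: tuple[str, ...]
    counts: np.ndarray          # per-code read counts
    unassigned: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.unassigned

    @property
    def fraction_identifiable(self) -> float:
        return float(self.counts.sum() / self.total) if self.total else float("nan")

    def to_frame(self):
        import pandas as pd

        rows = [{"code": c, "reads": int(n)} for c, n in zip(self.codes, self.counts)]
        rows.append({"code": "UNASSIGNED", "reads": self.unassigned})
        return pd.DataFrame(rows)


def validate_index_set(codes: list[str] | tuple[str, ...]) -> IndexSet:
    """Check a code set (equal lengths, ACGT, unique, pairwise Hamming >= 2)."""
    if not codes:
        raise IndexValidationError("empty index code list")
    lengths = {len(c) for c in codes}
    if len(lengths) != 1:
        raise IndexValidationError(f"codes of mixed lengths: {sorted(lengths)}")
    for c in codes:
        if set(c) - set("ACGT"):
            raise IndexValidationError(f"code {c!r} contains non-ACGT characters")
    if len(set(codes)) != len(codes):
        dupes = {c for c in codes if codes.count(c) > 1}
        raise IndexValidationError(f"duplicate codes: {sorted(dupes)}")
    min_d = len(codes[0]) if len(codes) > 1 else len(codes[0])
    worst = None
    mat = np.vstack([encode(c) for c in codes])
    for (i, a), (j, b) in combinations(enumerate(codes), 2):
        d = int((mat[i] != mat[j]).sum())
        if d < min_d:
            min_d, worst = d, (a, b)
    if len(codes) > 1 and min_d < 2:
        raise IndexValidationError(
            f"codes {worst[0]!r} and {worst[1]!r} are at Hamming distance {min_d} (< 2)"
        )
    return IndexSet(tuple(codes), len(codes[0]), min_d)


def generate_index_codes(
    n: int, length: int = 7, min_distance: int = 2, rng: np.random.Generator | None = None
) -> list[str]:
    """Greedily draw ``n`` random codes with pairwise Hamming distance >= min_distance."""
    rng = rng or np.random.default_rng(0)
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        cand = rng.integers(0, 4, length, dtype=np.uint8)
        if all(int((cand != c).sum()) >= min_distance for c in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 100_000 * n:
            raise RuntimeError("could not build index code set; relax constraints")
    return [decode(c) for c in chosen]


def assign_index(observed: str, index_set: IndexSet, max_mismatch: int = 1) -> str | None:
    """Assign one observed index; returns the code string or None (unassigned)."""
    if len(observed) != index_set.index_length:
        raise ValueError(
            f"observed index length {len(observed)} != code length {index_set.index_length}"
        )
    i = assign_indices(encode(observed)[None, :], index_set, max_mismatch)[0]
    return None if i == UNASSIGNED else index_set.codes[i]


def assign_indices(
    observed: np.ndarray, index_set: IndexSet, max_mismatch: int = 1
) -> np.ndarray:
    """Vectorized assignment of an (n, L) matrix of observed index bases.

    Returns per-read code indices, with :data:`UNASSIGNED` where no code is
    within ``max_mismatch`` or two codes tie at the minimum distance.  Base
    codes outside ACGT (e.g. N) mismatch every code.
    """
    observed = np.atleast_2d(observed)
    if observed.shape[1] != index_set.index_length:
        raise ValueError("observed index length != code length")
    codes = index_set.matrix  # (m, L)
    # distance matrix in chunks to bound memory
    n = observed.shape[0]
    out = np.full(n, UNASSIGNED, dtype=np.int64)
    for lo in range(0, n, 200_000):
        blk = observed[lo : lo + 200_000]
        d = (blk[:, None, :] != codes[None, :, :]).sum(axis=2)  # (b, m)
        best = d.argmin(axis=1)
        bestd = d[np.arange(len(blk)), best]
        within = bestd <= max_mismatch
        ties = (d == bestd[:, None]).sum(axis=1) > 1
        sel = within & ~ties
        out[lo : lo + len(blk)][sel] = best[sel]
    return out


def demultiplex(
    r1: np.ndarray,
    index_set: IndexSet,
    index_at_5prime: bool = False,
    max_mismatch: int = 1,
) -> tuple[np.ndarray, np.ndarray, DemuxResult]:
    """Split a read-1 base matrix by sample index.

    Returns ``(assignment, trimmed_r1, result)`` where assignment holds the
    per-read code index (or UNASSIGNED) and ``trimmed_r1`` is read 1 with the
    index bases removed.
    """
    k = index_set.index_length
    if r1.shape[1] <= k:
        raise ValueError("read 1 is not longer than the index")
    idx = r1[:, :k] if index_at_5prime else r1[:, -k:]
    trimmed = r1[:, k:] if index_at_5prime else r1[:, :-k]
    assignment = assign_indices(idx, index_set, max_mismatch)
    counts = np.bincount(assignment[assignment >= 0], minlength=len(index_set))
    result = DemuxResult(index_set.codes, counts, int((assignment == UNASSIGNED).sum()))
    return assignment, trimmed, result


def demultiplex_fastq(
    r1_path: str,
    r2_path: str,
    index_set: IndexSet,
    outdir: str,
    index_at_5prime: bool = False,
    max_mismatch: int = 1,
) -> DemuxResult:
    """File-level demultiplexing: per-sample FASTQ pairs named by code.

    The index is removed from both the sequence and quality strings of read 1;
    read 2 is written untouched.
    """
    import os

    from .io import read_fastq_pairs

    os.makedirs(outdir, exist_ok=True)
    k = index_set.index_length
    handles = {
        c: (
            open(os.path.join(outdir, f"{c}_R1.fastq"), "w"),
            open(os.path.join(outdir, f"{c}_R2.fastq"), "w"),
        )
        for c in index_set.codes
    }
    un = (
        open(os.path.join(outdir, "unassigned_R1.fastq"), "w"),
        open(os.path.join(outdir, "unassigned_R2.fastq"), "w"),
    )
    counts = np.zeros(len(index_set), dtype=np.int64)
    unassigned = 0
    try:
        for (n1, s1, q1), (n2, s2, q2) in read_fastq_pairs(r1_path, r2_path):
            obs = s1[:k] if index_at_5prime else s1[-k:]
            ts1 = s1[k:] if index_at_5prime else s1[:-k]
            tq1 = q1[k:] if index_at_5prime else q1[:-k]
            i = assign_indices(encode(obs)[None, :], index_set, max_mismatch)[0]
            if i == UNASSIGNED:
                unassigned += 1
                f1, f2 = un
                f1.write(f"@{n1}\n{s1}\n+\n{q1}\n")
            else:
                counts[i] += 1
                f1, f2 = handles[index_set.codes[i]]
                f1.write(f"@{n1}\n{ts1}\n+\n{tq1}\n")
            f2.write(f"@{n2}\n{s2}\n+\n{q2}\n")
    finally:
        for f1, f2 in list(handles.values()) + [un]:
            f1.close()
            f2.close()
    return DemuxResult(index_set.codes, counts, unassigned)
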