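"""In-memory container for aligned reads plus SAM text I/O.

Reads are stored as a dense matrix of base codes in *reference orientation*
(one row per read, one column per read offset), together with 0-based start
coordinates and a strand flag.  This mirrors what a SAM record carries (SEQ is
stored reference-oriented there too) while staying numpy-friendly: the error
model and the pileup builder consume these matrices directly.

Sequencing *cycle* mapping: a forward-strand read observes reference position
``start + i`` at cycle ``i + 1``; a reverse-strand read was sequenced from the
other end, so it observes ``start + i`` at cycle ``L - i``.

1 bp deletions are represented in-row with :data:`poolcap.seq.GAP_CODE`;
1 bp insertions live in a side table of ``(read_index, ref_offset, base)``
events (the inserted base follows reference offset ``ref_offset``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .seq import GAP_CODE, decode, encode

_EMPTY_INS = np.empty((0, 3), dtype=np.int64)


@dataclass
class AlignedReadSet:
    """A set of same-length reads aligned to one reference sequence."""

    ref_name: str
    ref: np.ndarray                    # (R,) uint8 reference bases
    seq: np.ndarray                    # (n, L) uint8, reference orientation
    start: np.ndarray                  # (n,) int64, 0-based leftmost ref offset
    strand: np.ndarray                 # (n,) uint8, 0 = forward, 1 = reverse
    names: list[str] | None = None
    insertions: np.ndarray = field(default_factory=lambda: _EMPTY_INS.copy())
    duplicate: np.ndarray | None = None  # optional bool flags (known duplicates)

    def __post_init__(self) -> None:
        self.seq = np.atleast_2d(np.asarray(self.seq, dtype=np.uint8))
        self.start = np.asarray(self.start, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype=np.uint8)
        if self.seq.shape[0] != self.start.shape[0]:
            raise ValueError("seq and start row counts differ")
        if np.any(self.start < 0) or np.any(self.start + self.read_length > len(self.ref)):
            raise ValueError("read overhangs reference end")

    @property
    def n_reads(self) -> int:
        return self.seq.shape[0]

    @property
    def read_length(self) -> int:
        return self.seq.shape[1]

    def cycle_of_offset(self, offsets: np.ndarray, strands: np.ndarray) -> np.ndarray:
        """1-based sequencing cycle for each (read offset, strand) pair."""
        L = self.read_length
        return np.where(strands == 0, offsets + 1, L - offsets)

    # ------------------------------------------------------------------ dedup
    def _row_keys(self) -> np.ndarray:
        n, L = self.seq.shape
        key = np.empty((n, L + 9), dtype=np.uint8)
        key[:, 0] = self.strand
        key[:, 1:9] = self.start.astype(">u8").view(np.uint8).reshape(n, 8)
        key[:, 9:] = self.seq
        return np.ascontiguousarray(key).view(
            np.dtype((np.void, key.shape[1]))
        ).ravel()

    def unique(self) -> tuple["AlignedReadSet", np.ndarray]:
        """Collapse identical (strand, start, sequence) reads.

        Returns the deduplicated set plus the multiplicity of each kept read.
        """
        keys = self._row_keys()
        _, first_idx, counts = np.unique(keys, return_index=True, return_counts=True)
        order = np.argsort(first_idx)  # preserve input order of first occurrences
        keep = first_idx[order]
        return self.subset(keep), counts[order]

    def mark_duplicates(self) -> np.ndarray:
        """Flag all but the first read of each (strand, start, sequence) group."""
        keys = self._row_keys()
        _, first = np.unique(keys, return_index=True)
        dup = np.ones(self.n_reads, dtype=bool)
        dup[first] = False
        self.duplicate = dup
        return dup

    def subset(self, idx: np.ndarray) -> "AlignedReadSet":
        idx = np.asarray(idx)
        if self.insertions.shape[0]:
            pos_of = np.full(self.n_reads, -1, dtype=np.int64)
            pos_of[idx] = np.arange(len(idx))
            m = pos_of[self.insertions[:, 0]] >= 0
            ins = self.insertions[m].copy()
            ins[:, 0] = pos_of[ins[:, 0]]
        else:
            ins = _EMPTY_INS.copy()
        return AlignedReadSet(
            ref_name=self.ref_name,
            ref=self.ref,
            seq=self.seq[idx],
            start=self.start[idx],
            strand=self.strand[idx],
            names=[self.names[i] for i in idx] if self.names is not None else None,
            insertions=ins,
            duplicate=None if self.duplicate is None else self.duplicate[idx],
        )

    def mismatch_counts(self) -> np.ndarray:
        """Substitution mismatches of every read against the reference.

        Gap (deletion) positions and insertion events are not counted here.
        """
        out = np.empty(self.n_reads, dtype=np.int64)
        L = self.read_length
        offs = np.arange(L)
        for lo in range(0, self.n_reads, 100_000):
            hi = min(lo + 100_000, self.n_reads)
            ref_block = self.ref[self.start[lo:hi, None] + offs]
            blk = self.seq[lo:hi]
            out[lo:hi] = ((blk != ref_block) & (blk != GAP_CODE)).sum(axis=1)
        return out

    # -------------------------------------------------------------------- SAM
    def to_sam(self, path: str) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": self.ref_name, "LN": int(len(self.ref))}],
        }
        ins_by_read: dict[int, list[tuple[int, int]]] = {}
        for r, off, base in self.insertions:
            ins_by_read.setdefault(int(r), []).append((int(off), int(base)))
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for i in range(self.n_reads):
                a = pysam.AlignedSegment(out.header)
                a.query_name = self.names[i] if self.names is not None else f"read{i}"
                a.reference_id = 0
                a.reference_start = int(self.start[i])
                a.mapping_quality = 60
                a.flag = 16 if self.strand[i] else 0
                if self.duplicate is not None and self.duplicate[i]:
                    a.flag |= 0x400
                seq_codes, cigar = _row_to_cigar(self.seq[i], ins_by_read.get(i, []))
                a.query_sequence = decode(seq_codes)
                a.cigartuples = cigar
                a.query_qualities = pysam.qualitystring_to_array("?" * len(seq_codes))
                out.write(a)

    @classmethod
    def from_sam(cls, path: str, ref: np.ndarray, ref_name: str | None = None) -> "AlignedReadSet":
        """Load a SAM file of uniform-span reads (CIGAR ops M, 1D, 1I, S)."""
        rows, starts, strands, names, ins_events, dups = [], [], [], [], [], []
        with pysam.AlignmentFile(path, "r", check_sq=False) as f:
            if ref_name is None and f.header.get("SQ"):
                ref_name = f.header["SQ"][0]["SN"]
            for a in f:
                if a.is_unmapped:
                    continue
                row, events = _cigar_to_row(a)
                rows.append(row)
                starts.append(a.reference_start)
                strands.append(1 if a.is_reverse else 0)
                names.append(a.query_name)
                dups.append(a.is_duplicate)
                for off, base in events:
                    ins_events.append((len(rows) - 1, off, base))
        if not rows:
            raise ValueError(f"no aligned reads in {path}")
        span = {len(r) for r in rows}
        if len(span) != 1:
            raise ValueError(f"reads with mixed aligned spans in {path}: {sorted(span)}")
        return cls(
            ref_name=ref_name or "ref",
            ref=ref,
            seq=np.vstack(rows),
            start=np.array(starts),
            strand=np.array(strands, dtype=np.uint8),
            names=names,
            insertions=np.array(ins_events, dtype=np.int64) if ins_events else _EMPTY_INS.copy(),
            duplicate=np.array(dups, dtype=bool),
        )


def _row_to_cigar(row: np.ndarray, ins: list[tuple[int, int]]) -> tuple[np.ndarray, list]:
    """Expand a reference-oriented row + insertion events into SEQ codes and CIGAR."""
    ins_at = dict(ins)
    out_codes: list[int] = []
    cigar: list[tuple[int, int]] = []

    def push(op: int, n: int = 1) -> None:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    for off, code in enumerate(row):
        if code == GAP_CODE:
            push(2)  # D
        else:
            out_codes.append(int(code))
            push(0)  # M
        if off in ins_at:
            out_codes.append(ins_at[off])
            push(1)  # I
    return np.array(out_codes, dtype=np.uint8), cigar


def _cigar_to_row(a: pysam.AlignedSegment) -> tuple[np.ndarray, list[tuple[int, int]]]:
    seq = encode(a.query_sequence)
    row: list[int] = []
    events: list[tuple[int, int]] = []
    q = 0
    for op, n in a.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            row.extend(seq[q : q + n])
            q += n
        elif op == 2:  # D
            row.extend([GAP_CODE] * n)
        elif op == 1:  # I
            if n != 1:
                raise ValueError(f"only 1 bp insertions supported, got {n}I in {a.query_name}")
            events.append((len(row) - 1, int(seq[q])))
            q += n
        elif op == 4:  # S
            q += n
        else:
            raise ValueError(f"unsupported CIGAR op {op} in {a.query_name}")
    return np.array(row, dtype=np.uint8), events
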