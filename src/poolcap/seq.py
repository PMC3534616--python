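"""Nucleotide encoding helpers shared across the package.

Bases are held as small unsigned integers (A=0, C=1, G=2, T=3) so that read
matrices, pileups and error-model tensors can be plain numpy arrays.  Code 4
marks a 1 bp deletion gap inside an aligned read; code 5 is reserved for N /
unknown.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
GAP_CODE = 4  # deleted base inside an aligned read
N_CODE = 5

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("-")] = GAP_CODE

_DECODE = np.frombuffer(b"ACGT-N", dtype=np.uint8)

_COMPLEMENT = np.array([3, 2, 1, 0, GAP_CODE, N_CODE], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a nucleotide string."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def complement(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes]


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance needs equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def gc_fraction(codes: np.ndarray) -> float:
    codes = np.asarray(codes)
    if codes.size == 0:
        return float("nan")
    return float(np.isin(codes, (1, 2)).mean())
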