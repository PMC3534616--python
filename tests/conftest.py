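import numpy as np
import pytest

from poolcap.pool_caller import PileupColumn


def make_column(
    ref: int = 0,
    read_length: int = 10,
    fwd: list[tuple[int, int, int]] = (),
    rev: list[tuple[int, int, int]] = (),
    pos: int = 1,
) -> PileupColumn:
    """Build a pileup column from (cycle, allele, count) triples per strand."""
    counts = np.zeros((2, read_length, 6), dtype=np.int32)
    for strand, triples in ((0, fwd), (1, rev)):
        for cycle, allele, n in triples:
            counts[strand, cycle - 1, allele] += n
    return PileupColumn("ref1", pos, ref, counts)


def uniform_column(
    ref: int,
    alt: int,
    n_ref_fwd: int,
    n_alt_fwd: int,
    n_ref_rev: int,
    n_alt_rev: int,
    read_length: int = 10,
    rng: np.random.Generator | None = None,
) -> PileupColumn:
    """Column with reads spread over random cycles."""
    rng = rng or np.random.default_rng(0)
    counts = np.zeros((2, read_length, 6), dtype=np.int32)
    for strand, (nr, na) in ((0, (n_ref_fwd, n_alt_fwd)), (1, (n_ref_rev, n_alt_rev))):
        for allele, n in ((ref, nr), (alt, na)):
            for c in rng.integers(0, read_length, n):
                counts[strand, c, allele] += 1
    return PileupColumn("ref1", 1, ref, counts)


@pytest.fixture(scope="session")
def flat_model():
    """Error model with known flat counts: every cell rate is exactly 1e-3.

    mismatches=99, opportunities=99996 + pseudocount 1 gives
    (99 + 1) / (99996 + 4) = 1e-3 per substitution cell.
    """
    from poolcap.error_model import ErrorModel

    m = ErrorModel(read_length=10, order=1, pseudocount=1.0)
    m.mism[:] = 99
    for b in range(4):
        m.mism[:, :, b, b] = 0
    m.opp[:] = 99_996
    return m
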