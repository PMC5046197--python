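import numpy as np
import pytest

from wmecphase import (
    Call,
    Fragment,
    FragmentMatrix,
    PhasingResult,
    read_fragments,
)

#: the 3-read x 2-SNP matrix used throughout: rows (1_9 1_9), (0_3 1_8), (- 0_8)
WORKED_EXAMPLE = (
    "#FRAGMAT v1 columns=2\n"
    "f1\t1:1:9,2:1:9\n"
    "f2\t1:0:3,2:1:8\n"
    "f3\t2:0:8\n"
)


@pytest.fixture
def worked_example() -> FragmentMatrix:
    return read_fragments(WORKED_EXAMPLE)


def make_random_matrix(
    rng: np.random.Generator,
    n_max: int = 8,
    m_max: int = 6,
    w_max: int = 10,
    allow_gaps: bool = True,
) -> FragmentMatrix:
    """Small random weighted fragment matrix with integer weights.

    Reads may skip columns inside their span (call gaps), exercising the
    span-active convention.
    """
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    frags = []
    for i in range(n):
        span = int(rng.integers(1, m + 1))
        start = int(rng.integers(0, m - span + 1))
        k = int(rng.integers(1, span + 1)) if allow_gaps else span
        cols = sorted(
            int(c) for c in rng.choice(range(start, start + span), size=k, replace=False)
        )
        calls = tuple(
            Call(column=c, allele=int(rng.integers(0, 2)), weight=int(rng.integers(1, w_max + 1)))
            for c in cols
        )
        frags.append(Fragment(read_id=f"r{i}", calls=calls))
    return FragmentMatrix(fragments=tuple(frags), num_columns=m)


def canonical(result: PhasingResult) -> tuple:
    """Hashable, fully-determined representation of a phasing result."""
    return (
        float(result.total_cost),
        tuple(result.read_part),
        result.haplotypes,
        tuple(result.corrections),
        tuple((b.start, b.stop, b.fragment_indices) for b in result.blocks),
    )
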