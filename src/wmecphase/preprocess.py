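"""Column activity, block decomposition, and coverage pruning.

A read is *span-active* at every column between its first and its last
call, inclusive: a paired-end fragment with an internal gap still ties the
columns it bridges together, and must be assigned to one haplotype
consistently across the gap.  Gap columns contribute zero correction cost
but do count toward coverage, because the DP carries the read's part
assignment through them.

Maximal runs of columns linked by read spans form independent *blocks*;
no read crosses a block boundary, so blocks phase independently (as if
they were different chromosomes) and costs add.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fragmat_io import Fragment, FragmentMatrix


@dataclass(frozen=True)
class ColumnActivity:
    """Ordered span-active fragment indices at one column."""

    column: int
    active_reads: tuple[int, ...]

    @property
    def coverage(self) -> int:
        return len(self.active_reads)


@dataclass(frozen=True)
class Block:
    """A maximal contiguous run of columns linked by read spans.

    `start`..`stop` is a half-open 0-based column range; `fragment_indices`
    are the reads whose whole span lies inside it.
    """

    start: int
    stop: int
    fragment_indices: tuple[int, ...]

    @property
    def columns(self) -> range:
        return range(self.start, self.stop)


def activity_profile(matrix: FragmentMatrix) -> list[ColumnActivity]:
    """Per-column ordered active-read sets (span-active convention)."""
    m = matrix.num_columns
    starts: list[list[int]] = [[] for _ in range(m)]
    stops: list[list[int]] = [[] for _ in range(m)]
    for i, frag in enumerate(matrix.fragments):
        starts[frag.first_column].append(i)
        stops[frag.last_column].append(i)
    profile: list[ColumnActivity] = []
    active: list[int] = []
    for j in range(m):
        for i in starts[j]:
            active.append(i)
        active.sort()
        profile.append(ColumnActivity(column=j, active_reads=tuple(active)))
        ending = set(stops[j])
        if ending:
            active = [i for i in active if i not in ending]
    return profile


def connected_blocks(matrix: FragmentMatrix) -> list[Block]:
    """Decompose the matrix into independent blocks.

    Columns of zero coverage separate blocks and belong to none; two
    adjacent covered columns stay in one block iff some read's span crosses
    the boundary between them.
    """
    m = matrix.num_columns
    if m == 0:
        return []
    coverage = [0] * m
    crosses = [False] * m  # crosses[j]: some span covers both j and j+1
    for frag in matrix.fragments:
        lo, hi = frag.first_column, frag.last_column
        for j in range(lo, hi + 1):
            coverage[j] += 1
        for j in range(lo, hi):
            crosses[j] = True

    blocks: list[Block] = []
    start = None
    for j in range(m):
        if coverage[j] == 0:
            if start is not None:
                blocks.append(_make_block(matrix, start, j))
                start = None
            continue
        if start is None:
            start = j
        elif not crosses[j - 1]:
            blocks.append(_make_block(matrix, start, j))
            start = j
    if start is not None:
        blocks.append(_make_block(matrix, start, m))
    return blocks


def _make_block(matrix: FragmentMatrix, start: int, stop: int) -> Block:
    idx = tuple(
        i
        for i, frag in enumerate(matrix.fragments)
        if frag.first_column >= start and frag.last_column < stop
    )
    return Block(start=start, stop=stop, fragment_indices=idx)


def prune_to_max_coverage(
    matrix: FragmentMatrix, max_cov: int, seed: int | None = None
) -> FragmentMatrix:
    """Drop reads greedily until every column's span coverage is <= max_cov.

    Scanning columns left to right, an over-covered column sheds the active
    read of smallest total call weight (ties: fewest calls, then highest
    fragment index) until the cap holds.  Surviving fragments are an
    unmodified subset of the input in their original order.  The rule is
    fully deterministic; `seed` is accepted for interface stability and has
    no effect.
    """
    del seed
    if max_cov < 1:
        raise ValueError(f"max_cov must be >= 1, got {max_cov}")
    frags = matrix.fragments
    spans = [(f.first_column, f.last_column) for f in frags]
    weight = [sum(c.weight for c in f.calls) for f in frags]
    ncalls = [len(f.calls) for f in frags]
    alive = set(range(len(frags)))

    for j in range(matrix.num_columns):
        active = [i for i in alive if spans[i][0] <= j <= spans[i][1]]
        while len(active) > max_cov:
            victim = min(active, key=lambda i: (weight[i], ncalls[i], -i))
            alive.discard(victim)
            active.remove(victim)
    survivors = tuple(frags[i] for i in sorted(alive))
    return FragmentMatrix(
        fragments=survivors,
        num_columns=matrix.num_columns,
        positions=matrix.positions,
    )
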