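"""Deterministic chunked map-reduce evaluation of a high-coverage column.

The bipartition space of a column is split into disjoint, contiguous
Gray-rank chunks.  Each chunk is evaluated independently (map phase):
local costs run incrementally from the chunk's own entry mask -- for the
second of two equal chunks of a 3-bit space that entry is Gray mask 110,
not 100 -- and the chunk records its own per-key minima for the next
column boundary in a private table, so no shared state is written.  A
sequential reduce then merges the local tables into the boundary
projection, breaking cost ties toward the numerically smallest mask.

Because the reduce is order-free, any execution schedule (any worker
count, any chunk interleaving) produces byte-identical tables to the
sequential path.  Columns below the coverage threshold are not worth the
task overhead and stay on the sequential path.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .dp_core import (
    ColumnCostTable,
    PhaserOptions,
    ProjectionTable,
    _bit_positions,
    _call_cost_arrays,
    _min_by_key,
    incremental_column_costs,
    inherited_costs,
    keys_for_masks,
    shared_reads,
)
from .fragmat_io import FragmentMatrix
from .preprocess import ColumnActivity


@dataclass
class ParallelOptions:
    """workers: map-phase parallelism; chunksize: Gray ranks per task;
    threshold: minimum column coverage worth parallelising (default 20)."""

    workers: int = 1
    chunksize: int = 4096
    threshold: int = 20

    def __post_init__(self):
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.chunksize < 1:
            raise ValueError("chunksize must be >= 1")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


@dataclass
class LocalMinTable:
    """One chunk's private per-key minima for the outgoing boundary."""

    chunk_id: int
    rank_range: tuple[int, int]
    min_cost: np.ndarray
    argmin_mask: np.ndarray


def chunk_ranks(c: int, chunksize: int) -> list[tuple[int, int]]:
    """Disjoint contiguous rank ranges covering [0, 2**c) in order."""
    if c < 0:
        raise ValueError("c must be >= 0")
    if chunksize < 1:
        raise ValueError("chunksize must be >= 1")
    size = 1 << c
    return [(s, min(s + chunksize, size)) for s in range(0, size, chunksize)]


def evaluate_chunk(
    matrix: FragmentMatrix,
    activity: ColumnActivity,
    rank_range: tuple[int, int],
    inherited: ProjectionTable | None,
    options: PhaserOptions,
    *,
    out_positions: list[int] | None = None,
    n_out_keys: int = 1,
    chunk_id: int = 0,
    cost_arrays: tuple[list[float], list[float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, LocalMinTable]:
    """Map-phase task: cumulative costs for one rank chunk + local minima.

    Pure function of its inputs.  `out_positions` are the bit positions
    (within this column's active set) of the reads shared with the next
    column; None means an empty shared set, whose single key records the
    chunk's global minimum.  Under symmetry halving the complement of each
    enumerated mask is folded into the local table as well, so downstream
    keys involving the fixed top read stay reachable.
    """
    c = activity.coverage
    halved = options.symmetry_halving and c > 0
    masks, local, _work = incremental_column_costs(
        matrix, activity, rank_range, options.all_het,
        halved=halved, cost_arrays=cost_arrays,
    )
    cum = local + inherited_costs(inherited, activity, masks)

    key_masks, key_costs = masks, cum
    if halved:
        full = np.int64((1 << c) - 1)
        key_masks = np.concatenate([masks, masks ^ full])
        key_costs = np.concatenate([cum, cum])
    if out_positions:
        keys = keys_for_masks(key_masks, out_positions)
    else:
        keys = np.zeros(len(key_masks), dtype=np.int64)
    min_cost, argmin = _min_by_key(key_masks, key_costs, keys, n_out_keys)
    local_table = LocalMinTable(
        chunk_id=chunk_id,
        rank_range=rank_range,
        min_cost=min_cost,
        argmin_mask=argmin,
    )
    return masks, cum, local_table


def reduce_locals(
    locals_: list[LocalMinTable],
    boundary: int,
    shared: tuple[int, ...],
) -> ProjectionTable:
    """Reduce phase: merge disjoint chunks' minima into one projection.

    Ties between chunks are broken by smallest mask, not arrival order,
    which is what makes the parallel contract deterministic.
    """
    if not locals_:
        raise ValueError("nothing to reduce")
    spans = sorted(t.rank_range for t in locals_)
    for (_, stop), (start, _) in zip(spans, spans[1:]):
        if start < stop:
            raise ValueError(f"overlapping chunk ranges around rank {start}")

    nkeys = len(locals_[0].min_cost)
    min_cost = np.full(nkeys, np.inf)
    argmin = np.full(nkeys, -1, dtype=np.int64)
    for t in locals_:
        better = (t.min_cost < min_cost) | (
            (t.min_cost == min_cost) & (t.argmin_mask >= 0) & (t.argmin_mask < argmin)
        )
        min_cost = np.where(better, t.min_cost, min_cost)
        argmin = np.where(better, t.argmin_mask, argmin)
    return ProjectionTable(
        boundary=boundary, shared_reads=shared, min_cost=min_cost, argmin_mask=argmin
    )


def parallel_column(
    matrix: FragmentMatrix,
    activity: ColumnActivity,
    inherited: ProjectionTable | None,
    options: PhaserOptions,
    *,
    next_activity: ColumnActivity | None = None,
) -> tuple[ColumnCostTable, ProjectionTable | None, int, int]:
    """One column evaluated by the chunked map-reduce contract.

    Returns (cost table, outgoing projection, bipartitions evaluated,
    tasks spawned); the first two are byte-identical to the sequential
    column step for every worker count and chunking.
    """
    popts = options.parallel or ParallelOptions()
    c = activity.coverage
    halved = options.symmetry_halving and c > 0
    nbits = c - 1 if halved else c
    chunks = chunk_ranks(nbits, popts.chunksize)

    if next_activity is not None:
        shared = shared_reads(activity, next_activity)
        out_positions = _bit_positions(activity, shared) if shared else None
        n_out_keys = 1 << len(shared)
    else:
        shared = ()
        out_positions = None
        n_out_keys = 1
    cost_arrays = _call_cost_arrays(matrix, activity)

    def run(args: tuple[int, tuple[int, int]]):
        cid, rng = args
        return evaluate_chunk(
            matrix, activity, rng, inherited, options,
            out_positions=out_positions, n_out_keys=n_out_keys,
            chunk_id=cid, cost_arrays=cost_arrays,
        )

    jobs = list(enumerate(chunks))
    if popts.workers > 1 and len(jobs) > 1:
        with ThreadPoolExecutor(max_workers=popts.workers) as pool:
            results = list(pool.map(run, jobs))
    else:
        results = [run(job) for job in jobs]

    costs = np.empty(1 << nbits)
    work = 0
    local_tables: list[LocalMinTable] = []
    for masks, cum, local_table in results:
        costs[masks] = cum
        work += len(masks)
        local_tables.append(local_table)
    table = ColumnCostTable(
        column=activity.column, coverage=c, halved=halved, costs=costs
    )
    proj = None
    if next_activity is not None:
        proj = reduce_locals(local_tables, next_activity.column, shared)
    return table, proj, work, len(jobs)
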