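"""The wMEC dynamic program over read bipartitions.

Phasing by weighted minimum error correction asks for a bipartition of the
reads into two haplotype classes, together with a minimum-weight set of
allele flips that makes each class conflict-free.  The state space at SNP
column j is the set of 2**c_j bipartitions of the c_j span-active reads;
the program sweeps columns left to right, carrying for each bipartition
the cheapest cumulative cost of any assignment history *compatible* with
it (compatible = agreeing on every read active in both columns).

Per column, the local cost of a bipartition (R, S) combines four sums
W0_R, W1_R, W0_S, W1_S -- the weight of flipping part R (or S) entirely to
allele 0 (or 1).  Bipartitions are enumerated in binary-reflected Gray
order so that consecutive masks move a single read between parts and the
four sums update in constant time.  The total work is sum_j 2**c_j, i.e.
exponential in coverage only, never in read length.

Two modes:

* default -- each part independently takes its cheaper consensus allele,
  so a site may come out homozygous;
* all-het -- the two parts are forced to complementary alleles at every
  site (the all-heterozygous assumption).

An optional symmetry-halving flag enumerates only the masks that place the
highest-indexed active read in part R, halving work per column; swapping
R and S leaves every cost invariant, so the optimum is unchanged.

Ties are always broken toward the numerically smallest mask, which makes
results bit-identical between sequential and chunked-parallel evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import CoverageLimitError
from .fragmat_io import FragmentMatrix
from .preprocess import Block, ColumnActivity, activity_profile, connected_blocks


# ---------------------------------------------------------------------------
# Options and bookkeeping


@dataclass
class PhaserOptions:
    """Knobs of the DP engine.

    all_het: force complementary alleles at every column.
    symmetry_halving: enumerate 2**(c-1) masks per column instead of 2**c.
    hard_coverage_limit: refuse columns whose table would exceed 2**limit
        entries (default 25, ~256 MiB of float64 per column).
    parallel: chunked-evaluation settings; None means the defaults of
        `parallel_engine.ParallelOptions` (workers=1, threshold=20).
    """

    all_het: bool = False
    symmetry_halving: bool = False
    hard_coverage_limit: int = 25
    parallel: object | None = None  # ParallelOptions; lazy to avoid an import cycle


@dataclass
class WorkCounters:
    """Accounting of DP effort, used by the work-conservation invariants."""

    bipartitions: int = 0
    parallel_columns: int = 0
    parallel_tasks: int = 0

    def merge(self, other: "WorkCounters") -> None:
        self.bipartitions += other.bipartitions
        self.parallel_columns += other.parallel_columns
        self.parallel_tasks += other.parallel_tasks


class Correction(NamedTuple):
    fragment: int
    column: int
    allele: int
    weight: float


@dataclass
class PhasingResult:
    """An optimal phasing: bipartition, haplotypes, corrections, cost.

    read_part[i] is the haplotype class (0/1) of fragment i.  Haplotypes
    are strings over {0, 1, -} of length m; '-' marks columns where the
    part carries no call (default mode) or that lie outside every block.
    total_cost equals the sum of correction weights.
    """

    total_cost: float
    read_part: list[int | None]
    haplotypes: tuple[str, str]
    corrections: list[Correction]
    blocks: list[Block]
    counters: WorkCounters = field(default_factory=WorkCounters)


@dataclass
class ColumnCostTable:
    """Minimum cumulative cost per bipartition mask of one column.

    costs[mask] indexes by plain mask value; Gray order is only the
    iteration order during construction.  Under symmetry halving the array
    holds the 2**(c-1) masks whose top active read sits in part R.
    """

    column: int
    coverage: int
    halved: bool
    costs: np.ndarray


@dataclass
class ProjectionTable:
    """Compatibility transfer across one column boundary.

    For the boundary between columns j-1 and j, keys enumerate assignments
    of the reads active in both; min_cost[key] is the cheapest column-j-1
    table entry projecting to that key and argmin_mask[key] the smallest
    full mask attaining it.
    """

    boundary: int  # the right column j
    shared_reads: tuple[int, ...]
    min_cost: np.ndarray
    argmin_mask: np.ndarray


# ---------------------------------------------------------------------------
# Elementary operations


def gray_rank_to_mask(rank: int) -> int:
    """Binary-reflected Gray code: rank XOR (rank >> 1)."""
    if rank < 0:
        raise ValueError("rank must be >= 0")
    return rank ^ (rank >> 1)


def _call_cost_arrays(
    matrix: FragmentMatrix, activity: ColumnActivity
) -> tuple[list[float], list[float]]:
    """Per active read: cost of forcing its call at this column to 0 / to 1.

    A read with no call here (gap column of its span) contributes (0, 0).
    """
    a0: list[float] = []
    a1: list[float] = []
    for idx in activity.active_reads:
        call = matrix.fragments[idx].call_at(activity.column)
        if call is None:
            a0.append(0.0)
            a1.append(0.0)
        elif call.allele == 1:
            a0.append(call.weight)
            a1.append(0.0)
        else:
            a0.append(0.0)
            a1.append(call.weight)
    return a0, a1


def _combine(w0r: float, w1r: float, w0s: float, w1s: float, all_het: bool) -> float:
    if all_het:
        return min(w1r + w0s, w0r + w1s)
    return min(w0r, w1r) + min(w0s, w1s)


def column_local_cost(
    matrix: FragmentMatrix,
    activity: ColumnActivity,
    mask: int,
    all_het: bool = False,
) -> float:
    """Local correction cost of one bipartition mask at one column.

    Direct four-sum evaluation; the DP itself uses the Gray-incremental
    path, for which this is the per-mask reference.
    """
    c = activity.coverage
    if not 0 <= mask < (1 << c):
        raise ValueError(f"mask {mask} out of range for coverage {c}")
    a0, a1 = _call_cost_arrays(matrix, activity)
    w0 = [0.0, 0.0]
    w1 = [0.0, 0.0]
    for k in range(c):
        p = (mask >> k) & 1
        w0[p] += a0[k]
        w1[p] += a1[k]
    return _combine(w0[0], w1[0], w0[1], w1[1], all_het)


def incremental_column_costs(
    matrix: FragmentMatrix,
    activity: ColumnActivity,
    rank_range: tuple[int, int],
    all_het: bool = False,
    *,
    halved: bool = False,
    cost_arrays: tuple[list[float], list[float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Local costs over a contiguous Gray-rank range, O(1) per step.

    The first mask of the range (the chunk entry point) is initialised
    from scratch; every following rank moves exactly one read between
    parts and updates the four part sums in constant time.  Returns
    (masks, costs, work) with work = range length.
    """
    start, stop = rank_range
    c = activity.coverage
    nbits = c - 1 if (halved and c > 0) else c
    size = 1 << nbits
    if not (0 <= start <= stop <= size):
        raise ValueError(f"rank range [{start}, {stop}) outside [0, {size})")

    a0, a1 = cost_arrays if cost_arrays is not None else _call_cost_arrays(matrix, activity)
    n = stop - start
    masks = np.empty(n, dtype=np.int64)
    costs = np.empty(n, dtype=np.float64)
    if n == 0:
        return masks, costs, 0

    mask = gray_rank_to_mask(start)
    w0 = [0.0, 0.0]
    w1 = [0.0, 0.0]
    for k in range(c):
        p = (mask >> k) & 1
        w0[p] += a0[k]
        w1[p] += a1[k]

    for t, rank in enumerate(range(start, stop)):
        if t:
            k = (rank & -rank).bit_length() - 1  # the single bit flipped
            p = (mask >> k) & 1
            q = p ^ 1
            w0[p] -= a0[k]
            w1[p] -= a1[k]
            w0[q] += a0[k]
            w1[q] += a1[k]
            mask ^= 1 << k
        masks[t] = mask
        costs[t] = _combine(w0[0], w1[0], w0[1], w1[1], all_het)
    return masks, costs, n


# ---------------------------------------------------------------------------
# Compatibility projection


def shared_reads(prev: ColumnActivity, nxt: ColumnActivity) -> tuple[int, ...]:
    """Reads active at both columns, in ascending fragment order."""
    nxt_set = set(nxt.active_reads)
    return tuple(i for i in prev.active_reads if i in nxt_set)


def _bit_positions(activity: ColumnActivity, reads: tuple[int, ...]) -> list[int]:
    where = {idx: k for k, idx in enumerate(activity.active_reads)}
    return [where[i] for i in reads]


def keys_for_masks(masks: np.ndarray, positions: list[int]) -> np.ndarray:
    """Project full masks onto a shared-read assignment key."""
    keys = np.zeros(len(masks), dtype=np.int64)
    for i, p in enumerate(positions):
        keys |= ((masks >> p) & np.int64(1)) << np.int64(i)
    return keys


def _table_masks_costs(table: ColumnCostTable) -> tuple[np.ndarray, np.ndarray]:
    """All full masks and their costs, expanding halved tables by symmetry."""
    masks = np.arange(len(table.costs), dtype=np.int64)
    costs = table.costs
    if table.halved and table.coverage > 0:
        full = np.int64((1 << table.coverage) - 1)
        masks = np.concatenate([masks, masks ^ full])
        costs = np.concatenate([costs, costs])
    return masks, costs


def _min_by_key(
    masks: np.ndarray, costs: np.ndarray, keys: np.ndarray, nkeys: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-key minimum cost with smallest-mask tie-breaking."""
    order = np.lexsort((masks, costs))
    uniq, first = np.unique(keys[order], return_index=True)
    min_cost = np.full(nkeys, np.inf)
    argmin = np.full(nkeys, -1, dtype=np.int64)
    sel = order[first]
    min_cost[uniq] = costs[sel]
    argmin[uniq] = masks[sel]
    return min_cost, argmin


def project_costs(
    table_prev: ColumnCostTable,
    act_prev: ColumnActivity,
    act_next: ColumnActivity,
) -> ProjectionTable:
    """Minimum cost and argmin mask per assignment of the shared reads.

    An empty shared set yields the single key 0 holding the global column
    minimum (this also anchors a block's first column: projecting over no
    reads inherits cost 0).
    """
    reads = shared_reads(act_prev, act_next)
    masks, costs = _table_masks_costs(table_prev)
    if not reads:
        order = np.lexsort((masks, costs))
        best = order[0]
        return ProjectionTable(
            boundary=act_next.column,
            shared_reads=(),
            min_cost=np.array([costs[best]]),
            argmin_mask=np.array([masks[best]], dtype=np.int64),
        )
    positions = _bit_positions(act_prev, reads)
    keys = keys_for_masks(masks, positions)
    min_cost, argmin = _min_by_key(masks, costs, keys, 1 << len(reads))
    return ProjectionTable(
        boundary=act_next.column,
        shared_reads=reads,
        min_cost=min_cost,
        argmin_mask=argmin,
    )


def inherited_costs(
    inherited: ProjectionTable | None,
    activity: ColumnActivity,
    masks: np.ndarray,
) -> np.ndarray:
    """Cost carried into column j for each mask, via the boundary projection."""
    if inherited is None or not inherited.shared_reads:
        base = 0.0 if inherited is None else float(inherited.min_cost[0])
        return np.full(len(masks), base)
    positions = _bit_positions(activity, inherited.shared_reads)
    keys = keys_for_masks(masks, positions)
    return inherited.min_cost[keys]


# ---------------------------------------------------------------------------
# Forward sweep


def dp_forward(
    matrix: FragmentMatrix,
    block: Block,
    options: PhaserOptions | None = None,
    activities: list[ColumnActivity] | None = None,
) -> tuple[list[ColumnCostTable], list[ProjectionTable], WorkCounters]:
    """Column-wise DP over one block.

    Returns per-column cumulative cost tables, the boundary projection
    tables between consecutive columns, and work counters.  Columns whose
    coverage reaches the parallel threshold are delegated to the chunked
    map-reduce engine; the result is independent of that delegation.
    """
    from .parallel_engine import ParallelOptions, parallel_column

    opts = options or PhaserOptions()
    popts = opts.parallel or ParallelOptions()
    if activities is None:
        activities = activity_profile(matrix)

    tables: list[ColumnCostTable] = []
    projections: list[ProjectionTable] = []
    counters = WorkCounters()
    inherited: ProjectionTable | None = None
    cols = list(block.columns)
    for t, j in enumerate(cols):
        act = activities[j]
        c = act.coverage
        if c > opts.hard_coverage_limit:
            raise CoverageLimitError(
                f"column {j}: coverage {c} needs a table of 2^{c} = {1 << c} "
                f"bipartitions, above the hard limit 2^{opts.hard_coverage_limit}"
            )
        next_act = activities[cols[t + 1]] if t + 1 < len(cols) else None
        if c >= popts.threshold:
            table, proj, work, ntasks = parallel_column(
                matrix, act, inherited, opts, next_activity=next_act
            )
            counters.parallel_columns += 1
            counters.parallel_tasks += ntasks
            counters.bipartitions += work
        else:
            halved = opts.symmetry_halving and c > 0
            masks, local, work = incremental_column_costs(
                matrix, act, (0, 1 << (c - 1 if halved else c)),
                opts.all_het, halved=halved,
            )
            counters.bipartitions += work
            cum = local + inherited_costs(inherited, act, masks)
            costs = np.empty(len(masks))
            costs[masks] = cum
            table = ColumnCostTable(column=j, coverage=c, halved=halved, costs=costs)
            proj = project_costs(table, act, next_act) if next_act is not None else None
        tables.append(table)
        if proj is not None:
            projections.append(proj)
        inherited = proj
    return tables, projections, counters


# ---------------------------------------------------------------------------
# Backtracking


def _column_targets(
    a0: list[float],
    a1: list[float],
    mask: int,
    all_het: bool,
) -> tuple[int | None, int | None]:
    """Consensus allele per part (None where the part has no call).

    Default mode picks each part's cheaper allele independently (ties to
    allele 0).  All-het mode picks the cheaper complementary orientation
    (ties to part R = 0); a part without calls takes the complement of the
    other part's allele.
    """
    c = len(a0)
    w0 = [0.0, 0.0]
    w1 = [0.0, 0.0]
    has = [False, False]
    for k in range(c):
        p = (mask >> k) & 1
        w0[p] += a0[k]
        w1[p] += a1[k]
        if a0[k] or a1[k]:
            has[p] = True
    if all_het:
        if not has[0] and not has[1]:
            return None, None
        # orientation (t_r, t_s): R all-0/S all-1 vs the complement
        if w0[0] + w1[1] <= w1[0] + w0[1]:
            return 0, 1
        return 1, 0
    tr = (0 if w0[0] <= w1[0] else 1) if has[0] else None
    ts = (0 if w0[1] <= w1[1] else 1) if has[1] else None
    return tr, ts


def backtrack(
    tables: list[ColumnCostTable],
    projections: list[ProjectionTable],
    activities: list[ColumnActivity],
    matrix: FragmentMatrix,
    block: Block,
    options: PhaserOptions | None = None,
) -> PhasingResult:
    """Recover an optimal phasing of one block from the DP tables.

    Selects the smallest final-column mask attaining the minimum, walks
    backwards through the boundary argmins, and re-derives per-column
    corrections as the cheaper flip set of the chosen bipartition.
    """
    opts = options or PhaserOptions()
    cols = list(block.columns)
    final = tables[-1].costs
    total = float(final.min())
    mask = int(np.argmin(final))  # first minimum = smallest mask

    chosen: dict[int, int] = {}
    for t in range(len(cols) - 1, -1, -1):
        j = cols[t]
        chosen[j] = mask
        if t > 0:
            proj = projections[t - 1]
            if proj.shared_reads:
                positions = _bit_positions(activities[j], proj.shared_reads)
                key = 0
                for i, p in enumerate(positions):
                    key |= ((mask >> p) & 1) << i
            else:
                key = 0
            mask = int(proj.argmin_mask[key])

    m = matrix.num_columns
    read_part: dict[int, int] = {}
    hap = [["-"] * m, ["-"] * m]
    corrections: list[Correction] = []
    check_cost = 0.0
    for j in cols:
        act = activities[j]
        cmask = chosen[j]
        for k, idx in enumerate(act.active_reads):
            read_part[idx] = (cmask >> k) & 1
        a0, a1 = _call_cost_arrays(matrix, act)
        tr, ts = _column_targets(a0, a1, cmask, opts.all_het)
        targets = (tr, ts)
        for p in (0, 1):
            if targets[p] is not None:
                hap[p][j] = str(targets[p])
        for k, idx in enumerate(act.active_reads):
            call = matrix.fragments[idx].call_at(j)
            if call is None:
                continue
            tgt = targets[(cmask >> k) & 1]
            if tgt is not None and call.allele != tgt:
                corrections.append(Correction(idx, j, call.allele, call.weight))
                check_cost += call.weight

    parts: list[int | None] = [None] * matrix.n
    for idx, p in read_part.items():
        parts[idx] = p
    return PhasingResult(
        total_cost=total,
        read_part=parts,
        haplotypes=("".join(hap[0]), "".join(hap[1])),
        corrections=corrections,
        blocks=[block],
    )


# ---------------------------------------------------------------------------
# Whole-matrix driver


def phase(
    matrix: FragmentMatrix, options: PhaserOptions | None = None
) -> PhasingResult:
    """Phase a whole fragment matrix: DP + backtrack per block, merged.

    Blocks share no reads, so their optima add and phasing them
    independently is exact.
    """
    opts = options or PhaserOptions()
    activities = activity_profile(matrix)
    blocks = connected_blocks(matrix)

    m = matrix.num_columns
    total = 0.0
    parts: list[int | None] = [None] * matrix.n
    hap1 = ["-"] * m
    hap2 = ["-"] * m
    corrections: list[Correction] = []
    counters = WorkCounters()
    for block in blocks:
        tables, projections, work = dp_forward(matrix, block, opts, activities)
        counters.merge(work)
        res = backtrack(tables, projections, activities, matrix, block, opts)
        total += res.total_cost
        corrections.extend(res.corrections)
        for i, p in enumerate(res.read_part):
            if p is not None:
                parts[i] = p
        for j in block.columns:
            hap1[j] = res.haplotypes[0][j]
            hap2[j] = res.haplotypes[1][j]
    return PhasingResult(
        total_cost=total,
        read_part=parts,
        haplotypes=("".join(hap1), "".join(hap2)),
        corrections=corrections,
        blocks=blocks,
        counters=counters,
    )
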