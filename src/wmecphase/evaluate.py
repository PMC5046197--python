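"""Independent scoring: brute-force wMEC oracle and phasing accuracy.

The oracle enumerates every read bipartition outright and is the
benchmark the dynamic program is validated against; it shares no code
path with the DP beyond the fragment data model.

Accuracy against a known truth is reported as three standard rates:

* switch error rate -- among consecutive phased heterozygous sites of a
  block, the fraction of adjacent pairs whose relative phase flips with
  respect to the truth;
* site error rate -- phased sites whose allele pair mismatches the truth
  under the best per-block haplotype orientation;
* phased fraction -- phased sites over phasable sites (every block column
  with coverage is phasable).
"""

from __future__ import annotations

from dataclasses import dataclass

from .dp_core import PhasingResult
from .fragmat_io import FragmentMatrix


@dataclass
class AccuracyReport:
    switch_error_rate: float
    site_error_rate: float
    phased_fraction: float
    switch_errors: int = 0
    switch_pairs: int = 0
    site_errors: int = 0
    phased_sites: int = 0
    phasable_sites: int = 0


def _per_column_part_sums(
    matrix: FragmentMatrix, read_part: list[int | None]
) -> dict[int, list[float]]:
    """For each column: [w0_R, w1_R, w0_S, w1_S] under a fixed assignment."""
    sums: dict[int, list[float]] = {}
    for i, frag in enumerate(matrix.fragments):
        p = read_part[i]
        if p is None:
            raise ValueError(f"fragment {i} has no part assignment")
        for call in frag.calls:
            w = sums.setdefault(call.column, [0.0, 0.0, 0.0, 0.0])
            # cost of forcing this call to 0 is paid when allele == 1
            if call.allele == 1:
                w[2 * p] += call.weight
            else:
                w[2 * p + 1] += call.weight
    return sums


def wmec_of_assignment(
    matrix: FragmentMatrix, read_part: list[int | None], all_het: bool = False
) -> float:
    """Total correction cost of a *given* bipartition, summed per column."""
    total = 0.0
    for w0r, w1r, w0s, w1s in _per_column_part_sums(matrix, read_part).values():
        if all_het:
            total += min(w1r + w0s, w0r + w1s)
        else:
            total += min(w0r, w1r) + min(w0s, w1s)
    return total


def brute_force_optimum(
    matrix: FragmentMatrix, all_het: bool = False, n_limit: int = 15
) -> tuple[float, tuple[int, ...]]:
    """Exhaustive minimum over all 2**n read bipartitions.

    Ties resolve to the smallest assignment bitmask (bit i = part of
    fragment i).  Refuses n above n_limit.
    """
    n = matrix.n
    if n > n_limit:
        raise ValueError(f"n = {n} exceeds brute-force limit {n_limit}")
    # per column: list of (fragment, cost_to_0, cost_to_1)
    per_col: dict[int, list[tuple[int, float, float]]] = {}
    for i, frag in enumerate(matrix.fragments):
        for call in frag.calls:
            a0 = call.weight if call.allele == 1 else 0.0
            a1 = call.weight if call.allele == 0 else 0.0
            per_col.setdefault(call.column, []).append((i, a0, a1))

    best_cost = float("inf")
    best_mask = 0
    for mask in range(1 << n):
        cost = 0.0
        for entries in per_col.values():
            w = [0.0, 0.0, 0.0, 0.0]
            for i, a0, a1 in entries:
                p = (mask >> i) & 1
                w[2 * p] += a0
                w[2 * p + 1] += a1
            if all_het:
                cost += min(w[1] + w[2], w[0] + w[3])
            else:
                cost += min(w[0], w[1]) + min(w[2], w[3])
            if cost >= best_cost:
                break
        if cost < best_cost:
            best_cost = cost
            best_mask = mask
    parts = tuple((best_mask >> i) & 1 for i in range(n))
    return best_cost, parts


def accuracy(
    result: PhasingResult, truth_haplotypes: tuple[str, str]
) -> AccuracyReport:
    """Score a phasing against true haplotypes, pooled over blocks.

    Metrics are invariant under a global swap of the predicted (or true)
    haplotype pair because each block is scored under its own best
    orientation.
    """
    t1, t2 = truth_haplotypes
    p1, p2 = result.haplotypes
    if len(t1) != len(p1) or len(t2) != len(p1):
        raise ValueError(
            f"truth haplotype length {len(t1)} does not match result length {len(p1)}"
        )

    switch_errors = switch_pairs = 0
    site_errors = phased = phasable = 0
    for block in result.blocks:
        cols = list(block.columns)
        phasable += len(cols)
        phased_cols = [j for j in cols if p1[j] in "01" and p2[j] in "01"]
        phased += len(phased_cols)

        # best orientation for this block (identity vs swapped pair)
        mism_id = sum(1 for j in phased_cols if (p1[j], p2[j]) != (t1[j], t2[j]))
        mism_sw = sum(1 for j in phased_cols if (p1[j], p2[j]) != (t2[j], t1[j]))
        site_errors += min(mism_id, mism_sw)

        het_cols = [j for j in phased_cols if p1[j] != p2[j]]
        flips = [p1[j] != t1[j] for j in het_cols]
        switch_pairs += max(0, len(flips) - 1)
        switch_errors += sum(1 for a, b in zip(flips, flips[1:]) if a != b)

    return AccuracyReport(
        switch_error_rate=switch_errors / switch_pairs if switch_pairs else 0.0,
        site_error_rate=site_errors / phased if phased else 0.0,
        phased_fraction=phased / phasable if phasable else 0.0,
        switch_errors=switch_errors,
        switch_pairs=switch_pairs,
        site_errors=site_errors,
        phased_sites=phased,
        phasable_sites=phasable,
    )
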