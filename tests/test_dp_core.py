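import numpy as np
import pytest

from wmecphase import (
    Call,
    CoverageLimitError,
    Fragment,
    FragmentMatrix,
    PhaserOptions,
    activity_profile,
    backtrack,
    brute_force_optimum,
    column_local_cost,
    connected_blocks,
    dp_forward,
    gray_rank_to_mask,
    incremental_column_costs,
    phase,
    project_costs,
    wmec_of_assignment,
)

from conftest import canonical, make_random_matrix


def naive_cost(matrix, activity, mask, all_het=False):
    """Direct four-sum recomputation, independent of the engine's helpers."""
    w = {(p, a): 0.0 for p in (0, 1) for a in (0, 1)}
    for k, idx in enumerate(activity.active_reads):
        call = matrix.fragments[idx].call_at(activity.column)
        if call is None:
            continue
        part = (mask >> k) & 1
        w[(part, 1 - call.allele)] += call.weight  # cost of flipping to 1-allele
    if all_het:
        return min(w[(0, 1)] + w[(1, 0)], w[(0, 0)] + w[(1, 1)])
    return min(w[(0, 0)], w[(0, 1)]) + min(w[(1, 0)], w[(1, 1)])


class TestGrayCode:
    def test_entry_point_of_second_chunk_is_110(self):
        assert gray_rank_to_mask(4) == 0b110

    def test_rank_zero(self):
        assert gray_rank_to_mask(0) == 0

    def test_consecutive_masks_differ_by_one_bit(self):
        masks = [gray_rank_to_mask(r) for r in range(1 << 10)]
        assert all(bin(a ^ b).count("1") == 1 for a, b in zip(masks, masks[1:]))
        assert len(set(masks)) == 1 << 10  # a permutation of the mask space

    def test_rejects_negative_rank(self):
        with pytest.raises(ValueError):
            gray_rank_to_mask(-1)


class TestColumnLocalCost:
    def test_worked_example_same_part_costs_three(self, worked_example):
        act = activity_profile(worked_example)[0]
        # f1 (allele 1, w9) and f2 (allele 0, w3) together: flip f2 for 3
        assert column_local_cost(worked_example, act, 0b00) == 3
        assert column_local_cost(worked_example, act, 0b11) == 3

    def test_conflict_free_split_costs_zero(self, worked_example):
        act = activity_profile(worked_example)[0]
        assert column_local_cost(worked_example, act, 0b01) == 0
        assert column_local_cost(worked_example, act, 0b10) == 0

    @pytest.mark.parametrize("all_het", [False, True])
    def test_matches_direct_recomputation(self, all_het):
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 200:
            mat = make_random_matrix(rng, n_max=8, m_max=5)
            acts = activity_profile(mat)
            act = acts[int(rng.integers(0, mat.m))]
            if act.coverage == 0:
                continue
            mask = int(rng.integers(0, 1 << act.coverage))
            assert column_local_cost(mat, act, mask, all_het) == naive_cost(
                mat, act, mask, all_het
            )
            checked += 1


class TestIncrementalCosts:
    def test_full_range_matches_per_mask(self, worked_example):
        act = activity_profile(worked_example)[1]
        masks, costs, work = incremental_column_costs(worked_example, act, (0, 8))
        assert work == 8
        for mask, cost in zip(masks, costs):
            assert cost == column_local_cost(worked_example, act, int(mask))

    def test_length_one_range_is_the_entry_mask(self, worked_example):
        act = activity_profile(worked_example)[1]
        masks, costs, _ = incremental_column_costs(worked_example, act, (5, 6))
        assert masks[0] == gray_rank_to_mask(5)
        assert costs[0] == column_local_cost(worked_example, act, int(masks[0]))

    @pytest.mark.parametrize("all_het", [False, True])
    def test_random_subranges_match_recomputation(self, all_het):
        rng = np.random.default_rng(31)
        for _ in range(40):
            mat = make_random_matrix(rng, n_max=8, m_max=4)
            acts = activity_profile(mat)
            act = max(acts, key=lambda a: a.coverage)
            size = 1 << act.coverage
            lo = int(rng.integers(0, size))
            hi = int(rng.integers(lo, size + 1))
            masks, costs, _ = incremental_column_costs(mat, act, (lo, hi), all_het)
            for mask, cost in zip(masks, costs):
                assert cost == naive_cost(mat, act, int(mask), all_het)


class TestProjection:
    def test_worked_example_boundary(self, worked_example):
        acts = activity_profile(worked_example)
        block = connected_blocks(worked_example)[0]
        tables, _, _ = dp_forward(worked_example, block)
        proj = project_costs(tables[0], acts[0], acts[1])
        assert proj.shared_reads == (0, 1)
        # keys 00 and 11 keep f1 and f2 together: cheapest history costs 3
        assert list(proj.min_cost) == [3, 0, 0, 3]
        assert list(proj.argmin_mask) == [0, 1, 2, 3]

    def test_identical_active_sets_project_identically(self):
        frags = (
            Fragment("a", (Call(0, 1, 4), Call(1, 0, 2))),
            Fragment("b", (Call(0, 0, 3), Call(1, 1, 5))),
        )
        mat = FragmentMatrix(frags, 2)
        acts = activity_profile(mat)
        tables, _, _ = dp_forward(mat, connected_blocks(mat)[0])
        proj = project_costs(tables[0], acts[0], acts[1])
        assert list(proj.min_cost) == list(tables[0].costs)
        assert list(proj.argmin_mask) == [0, 1, 2, 3]

    def test_matches_brute_force_projection(self):
        rng = np.random.default_rng(41)
        for _ in range(40):
            mat = make_random_matrix(rng, n_max=7, m_max=5)
            acts = activity_profile(mat)
            for block in connected_blocks(mat):
                cols = list(block.columns)
                if len(cols) < 2:
                    continue
                tables, _, _ = dp_forward(mat, block)
                for t in range(len(cols) - 1):
                    prev, nxt = acts[cols[t]], acts[cols[t + 1]]
                    proj = project_costs(tables[t], prev, nxt)
                    shared = proj.shared_reads
                    pos = [prev.active_reads.index(i) for i in shared]
                    for key in range(1 << len(shared)):
                        projecting = [
                            mask
                            for mask in range(len(tables[t].costs))
                            if all(((mask >> p) & 1) == ((key >> b) & 1)
                                   for b, p in enumerate(pos))
                        ]
                        expected = min(tables[t].costs[m2] for m2 in projecting)
                        assert proj.min_cost[key] == expected
                        assert proj.argmin_mask[key] == min(
                            m2 for m2 in projecting
                            if tables[t].costs[m2] == expected
                        )


class TestForwardAndBacktrack:
    def test_worked_example_optimum_is_three(self, worked_example):
        block = connected_blocks(worked_example)[0]
        tables, _, counters = dp_forward(worked_example, block)
        assert tables[-1].costs.min() == 3
        assert counters.bipartitions == 2**2 + 2**3

    def test_worked_example_solution_structure(self, worked_example):
        res = phase(worked_example)
        assert res.total_cost == 3
        assert res.read_part[0] == res.read_part[1] != res.read_part[2]
        assert [tuple(c) for c in res.corrections] == [(1, 0, 0, 3.0)]

    def test_conflict_free_matrix_costs_zero(self):
        frags = (
            Fragment("a", (Call(0, 1, 5), Call(1, 0, 5))),
            Fragment("b", (Call(0, 0, 5), Call(1, 1, 5))),
            Fragment("c", (Call(1, 0, 5), Call(2, 1, 5))),
        )
        res = phase(FragmentMatrix(frags, 3))
        assert res.total_cost == 0 and not res.corrections

    def test_single_read_needs_no_corrections(self):
        mat = FragmentMatrix((Fragment("a", (Call(0, 1, 5), Call(1, 1, 2))),), 2)
        res = phase(mat)
        assert res.total_cost == 0 and res.haplotypes[res.read_part[0]] == "11"

    @pytest.mark.parametrize("all_het", [False, True])
    def test_matches_brute_force_oracle(self, all_het):
        rng = np.random.default_rng(51)
        for _ in range(60):
            mat = make_random_matrix(rng)
            opt, _ = brute_force_optimum(mat, all_het)
            assert phase(mat, PhaserOptions(all_het=all_het)).total_cost == opt

    def test_refuses_over_the_hard_coverage_limit(self):
        frags = tuple(Fragment(f"r{i}", (Call(0, 1, 1),)) for i in range(5))
        mat = FragmentMatrix(frags, 1)
        with pytest.raises(CoverageLimitError, match="column 0"):
            phase(mat, PhaserOptions(hard_coverage_limit=4))


class TestInvariants:
    def test_mask_complement_symmetry(self, worked_example):
        acts = activity_profile(worked_example)
        for act in acts:
            full = (1 << act.coverage) - 1
            for mask in range(1 << act.coverage):
                assert column_local_cost(worked_example, act, mask) == \
                    column_local_cost(worked_example, act, mask ^ full)

    def test_symmetry_halving_gives_identical_cost_and_result(self):
        rng = np.random.default_rng(61)
        for _ in range(40):
            mat = make_random_matrix(rng)
            for all_het in (False, True):
                full = phase(mat, PhaserOptions(all_het=all_het))
                half = phase(mat, PhaserOptions(all_het=all_het, symmetry_halving=True))
                assert canonical(full) == canonical(half)

    def test_all_het_cost_dominates_default(self):
        rng = np.random.default_rng(71)
        for _ in range(50):
            mat = make_random_matrix(rng)
            assert phase(mat, PhaserOptions(all_het=True)).total_cost >= \
                phase(mat).total_cost

    def test_removing_a_read_never_raises_cost(self):
        rng = np.random.default_rng(81)
        for _ in range(50):
            mat = make_random_matrix(rng, n_max=6, m_max=5)
            if mat.n < 2:
                continue
            drop = int(rng.integers(0, mat.n))
            sub = FragmentMatrix(
                tuple(f for i, f in enumerate(mat.fragments) if i != drop),
                mat.num_columns,
            )
            assert phase(sub).total_cost <= phase(mat).total_cost

    def test_cost_conservation_and_conflict_freeness(self):
        rng = np.random.default_rng(91)
        for _ in range(50):
            mat = make_random_matrix(rng)
            for all_het in (False, True):
                res = phase(mat, PhaserOptions(all_het=all_het))
                assert res.total_cost == sum(c.weight for c in res.corrections)
                # re-score the returned assignment independently
                assert wmec_of_assignment(mat, res.read_part, all_het) == res.total_cost
                # applying the corrections leaves a conflict-free matrix
                flips = {(c.fragment, c.column) for c in res.corrections}
                fixed = FragmentMatrix(
                    tuple(
                        Fragment(
                            f.read_id,
                            tuple(
                                Call(c.column, c.allele ^ ((i, c.column) in flips), c.weight)
                                for c in f.calls
                            ),
                        )
                        for i, f in enumerate(mat.fragments)
                    ),
                    mat.num_columns,
                )
                assert wmec_of_assignment(fixed, res.read_part, all_het) == 0
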