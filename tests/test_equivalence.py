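import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equirep.equivalence import (
    EquivClasses,
    EquivMatrix,
    build_classes,
    build_initial_matrix,
    extract_paths,
    find_local_maxima,
    refine_matrix,
)
from equirep.region_detect import self_alignment_table
from equirep.simulate import random_dna


def _table(cells, n=8):
    D = np.zeros((n + 1, n + 1), dtype=np.int32)
    for (i, j), v in cells.items():
        D[i, j] = v
    return D


class TestLocalMaxima:
    def test_single_nonzero_cell(self):
        assert find_local_maxima(_table({(2, 4): 3})) == [(2, 4)]

    def test_all_zero_table(self):
        assert find_local_maxima(_table({})) == []

    def test_plateau_keeps_row_major_first(self):
        D = _table({(2, 4): 3, (2, 7): 3})  # 3 apart, one 7x7 window
        assert find_local_maxima(D) == [(2, 4)]

    def test_distant_equal_maxima_both_kept(self):
        D = _table({(1, 8): 3, (7, 8): 3}, n=20)
        assert find_local_maxima(D) == [(1, 8), (7, 8)]

    def test_window_validation(self):
        with pytest.raises(ValueError):
            find_local_maxima(_table({}), window=4)


class TestInitialMatrix:
    def test_exact_three_copy_repeat(self):
        """(8-mer)^3: the copy-to-copy path writes M[i, i+8] for i=1..16
        with score 32; the offset-16 path scores 16 < 25 and is dropped."""
        S = "ACGTTGCA" * 3
        D = self_alignment_table(S)
        M, paths = build_initial_matrix(D, S, find_local_maxima(D))
        assert sorted(M.entries) == [(i, i + 8) for i in range(1, 17)]
        assert set(M.entries.values()) == {32.0}
        assert len(paths) == 1 and paths[0].score == 32

    def test_low_scoring_path_discarded(self):
        S = "ACGTACGT"  # single 4-mer pair: score 8 < 25
        D = self_alignment_table(S)
        M, paths = build_initial_matrix(D, S, find_local_maxima(D))
        assert M.entries == {} and paths == []

    def test_second_traceback_terminates_on_existing_path(self):
        """A traceback that immediately meets a claimed cell scores the
        differential D[p,q]-D[k,l] (here zero) and leaves M untouched."""
        S = "ACGTTGCA" * 3
        D = self_alignment_table(S)
        M1, p1 = build_initial_matrix(D, S, [(16, 24)], min_path_score=1)
        M2, p2 = build_initial_matrix(D, S, [(16, 24), (12, 20)], min_path_score=1)
        assert len(p1) == len(p2) == 1
        assert M2.entries == M1.entries


class TestRefine:
    def test_symmetric_triple_exactly_invariant(self):
        M = EquivMatrix(3, {(1, 2): 1.0, (1, 3): 1.0, (2, 3): 1.0})
        out = refine_matrix(M, rounds=1)
        assert out.entries == {(1, 2): 1.0, (1, 3): 1.0, (2, 3): 1.0}

    def test_mixed_fixture_hand_computed(self):
        """Triple-supported pairs gain mass relative to the unsupported
        pair (1,6) under the geometric-mean row normalization."""
        M = EquivMatrix(6, {(1, 2): 1.0, (1, 3): 1.0, (2, 3): 1.0, (1, 6): 1.0})
        out = refine_matrix(M, rounds=1).entries
        assert out[(1, 2)] == pytest.approx(2 * (0.6 * 0.5) ** 0.5, abs=1e-12)
        assert out[(1, 3)] == pytest.approx(2 * (0.6 * 0.5) ** 0.5, abs=1e-12)
        assert out[(2, 3)] == pytest.approx(1.0, abs=1e-12)
        assert out[(1, 6)] == pytest.approx(0.6**0.5, abs=1e-12)

    def test_empty_matrix(self):
        assert refine_matrix(EquivMatrix(5, {}), rounds=3).entries == {}

    def test_entry_without_triple_only_rescaled(self):
        M = EquivMatrix(9, {(1, 5): 2.0, (3, 9): 7.0})
        out = refine_matrix(M, rounds=4).entries
        assert out == {(1, 5): 2.0, (3, 9): 7.0}  # factors are all 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_support_and_sign_preserved(self, seed):
        """Refinement never creates or removes entries and keeps them
        positive; per-position row mass is conserved up to the symmetric
        normalization's approximation."""
        rng = np.random.default_rng(seed)
        n = 12
        cells = {}
        for _ in range(rng.integers(3, 15)):
            i, j = sorted(rng.choice(np.arange(1, n + 1), 2, replace=False))
            cells[(int(i), int(j))] = float(rng.integers(1, 10))
        M = EquivMatrix(n, cells)
        out = refine_matrix(M, rounds=3)
        assert set(out.entries) == set(cells)
        assert all(v > 0 for v in out.entries.values())
        before, after = sum(cells.values()), sum(out.entries.values())
        assert after == pytest.approx(before, rel=0.2)


class TestExtractPaths:
    def test_single_diagonal_run(self):
        M = EquivMatrix(11, {(1, 9): 2.0, (2, 10): 2.0, (3, 11): 2.0})
        (p,) = extract_paths(M)
        assert p.cells == ((1, 9), (2, 10), (3, 11)) and p.score == 6.0

    def test_below_threshold_isolated_cell(self):
        assert extract_paths(EquivMatrix(12, {(5, 12): 0.5})) == []

    def test_two_disjoint_runs_are_disjoint_paths(self):
        M = EquivMatrix(40, {(1, 9): 2.0, (2, 10): 2.0, (21, 29): 3.0, (22, 30): 3.0})
        paths = extract_paths(M)
        assert len(paths) == 2
        cells = [c for p in paths for c in p.cells]
        assert len(cells) == len(set(cells))

    def test_horizontal_and_vertical_moves_connect(self):
        M = EquivMatrix(12, {(1, 9): 1.0, (1, 10): 1.0, (2, 10): 1.0})
        (p,) = extract_paths(M)
        assert p.score == 3.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_peeled_paths_partition_their_cells(self, seed):
        rng = np.random.default_rng(seed)
        cells = {
            (int(i), int(i + d)): float(rng.integers(1, 5))
            for i, d in zip(
                rng.integers(1, 30, size=15), rng.integers(6, 20, size=15)
            )
        }
        M = EquivMatrix(60, cells)
        paths = extract_paths(M, min_score=1.0)
        seen = [c for p in paths for c in p.cells]
        assert len(seen) == len(set(seen))
        for p in paths:
            assert p.score == pytest.approx(sum(cells[c] for c in p.cells))
            assert p.score >= 1.0
            for (i0, j0), (i1, j1) in zip(p.cells, p.cells[1:]):
                assert (i1 - i0, j1 - j0) in ((1, 1), (1, 0), (0, 1))


class TestBuildClasses:
    def test_three_copy_classes(self):
        S = "ACGTTGCA" * 3
        M = EquivMatrix(
            24,
            {(i, i + 8): 2.0 for i in range(1, 17)},
        )
        paths = extract_paths(M)
        classes = build_classes(paths, M, S)
        assert set(classes.positions) >= {(1, 9, 17), (2, 10, 18), (3, 11, 19)}

    def test_min_separation_blocks_close_union(self):
        S = "ACGTACGT"
        M = EquivMatrix(8, {(3, 6): 9.0})
        classes = build_classes(extract_paths(M), M, S)
        assert (3,) in classes.positions and (6,) in classes.positions

    def test_majority_letter_and_tie_rules(self):
        assert EquivClasses.from_partition([[1, 2, 3]], "AAC").letters == ("A",)
        assert EquivClasses.from_partition([[1, 2]], "CA").letters == ("A",)  # tie
        assert EquivClasses.from_partition([[1, 2, 3]], "NNC").letters == ("C",)

    def test_separation_invariant_holds_everywhere(self):
        rng = np.random.default_rng(3)
        S = random_dna(rng, 60)
        cells = {
            (int(i), int(i + d)): float(rng.integers(1, 9))
            for i, d in zip(rng.integers(1, 50, size=30), rng.integers(4, 12, size=30))
            if i + d <= 60
        }
        M = EquivMatrix(60, cells)
        classes = build_classes(extract_paths(M, min_score=0.5), M, S)
        for members in classes.positions:
            gaps = [b - a for a, b in zip(members, members[1:])]
            assert all(g > 5 for g in gaps)


@pytest.mark.parametrize("unit_len,copies", [(7, 3), (8, 3), (12, 4), (30, 5)])
def test_error_free_classes_are_congruent_modulo_unit(unit_len, copies):
    """On error-free (U)^m every class is a subset of one residue class
    modulo |U|: equivalence recovers the true unit phase exactly."""
    rng = np.random.default_rng(unit_len * 100 + copies)
    S = random_dna(rng, unit_len) * copies
    D = self_alignment_table(S)
    M, _ = build_initial_matrix(D, S, find_local_maxima(D))
    refined = refine_matrix(M)
    classes = build_classes(extract_paths(refined), refined, S)
    for members in classes.positions:
        assert len({p % unit_len for p in members}) == 1
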