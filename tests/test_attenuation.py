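import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_de_table
from dsp_attenuation.attenuation import (
    ContingencyMatrix,
    OverlapCounts,
    build_contingency,
    direction_independence_table,
    expected_null_opposite,
    fisher_exact,
    overlap_directions,
    permutation_null,
)
from dsp_attenuation.errors import AlignmentError


def fisher_oracle(table) -> float:
    """Exhaustive two-sided Fisher p: enumerate all tables with the observed
    margins and sum the hypergeometric probabilities of those no more
    probable than the observed table. Independent of any library routine."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P[X11 = x] with margins fixed
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


UNIVERSE = [f"g{i}" for i in range(30)]


class TestOverlapDirections:
    def test_disjoint_deg_sets_have_no_overlap(self):
        space = make_de_table(UNIVERSE, {"g0": 1, "g1": -1})
        buoe = make_de_table(UNIVERSE, {"g5": 1, "g6": -1})
        counts = overlap_directions(space, buoe)
        assert (counts.n_opposite, counts.n_same) == (0, 0)
        assert counts.N == 4

    def test_hand_enumerated_example(self):
        # space {A:+, B:-}, BuOE {A:-, B:-}: A opposite, B same
        space = make_de_table(UNIVERSE, {"g0": 1, "g1": -1})
        buoe = make_de_table(UNIVERSE, {"g0": -1, "g1": -1})
        counts = overlap_directions(space, buoe)
        assert counts.n_opposite == 1
        assert counts.n_same == 1
        assert counts.n_space_degs == 2
        assert counts.n_buoe_degs == 2

    def test_mismatched_universes_rejected(self):
        space = make_de_table(UNIVERSE, {})
        buoe = make_de_table(UNIVERSE[:-2], {})
        with pytest.raises(AlignmentError, match="2"):
            overlap_directions(space, buoe)

    def test_direction_independence_table_counts_sign_pairs(self):
        space = make_de_table(UNIVERSE, {"g0": 1, "g1": -1, "g2": 1})
        buoe = make_de_table(UNIVERSE, {"g0": -1, "g1": -1, "g2": 1, "g9": 1})
        table = direction_independence_table(space, buoe)
        # rows: space up/down; cols: buoe up/down
        np.testing.assert_array_equal(table, [[1, 1], [0, 1]])


class TestBuildContingency:
    def test_direct_substitution(self):
        m = build_contingency(
            OverlapCounts(n_opposite=20, n_same=5, n_space_degs=60, n_buoe_degs=40)
        )
        np.testing.assert_array_equal(m.as_array(), [[20, 80], [5, 95]])

    def test_empty_overlap(self):
        m = build_contingency(
            OverlapCounts(n_opposite=0, n_same=0, n_space_degs=30, n_buoe_degs=20)
        )
        np.testing.assert_array_equal(m.as_array(), [[0, 50], [0, 50]])

    @given(
        st.integers(0, 200),
        st.integers(0, 200),
        st.integers(0, 100),
        st.integers(0, 100),
    )
    @settings(deadline=None, max_examples=200)
    def test_row_sums_equal_N_on_fuzzed_inputs(self, n_space, n_buoe, opp, same):
        if opp + same > min(n_space, n_buoe):
            with pytest.raises(ValueError):
                OverlapCounts(opp, same, n_space, n_buoe)
            return
        overlap = OverlapCounts(opp, same, n_space, n_buoe)
        m = build_contingency(overlap)
        assert m.X11 + m.X12 == overlap.N
        assert m.X21 + m.X22 == overlap.N
        assert m.X12 == overlap.N - m.X11
        assert m.X22 == overlap.N - m.X21


class TestFisherExact:
    def test_identical_rows_give_p_one(self):
        assert fisher_exact(ContingencyMatrix(0, 50, 0, 50)) == 1.0

    def test_all_zero_matrix_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert fisher_exact(ContingencyMatrix(0, 0, 0, 0)) == 1.0

    def test_reference_table_matches_oracle(self):
        m = ContingencyMatrix(20, 80, 5, 95)
        assert fisher_exact(m) == pytest.approx(fisher_oracle([[20, 80], [5, 95]]), abs=1e-12)
        assert m.fisher_p is not None

    @pytest.mark.parametrize(
        "table",
        [[[1, 9], [11, 3]], [[0, 10], [12, 2]], [[5, 0], [0, 5]], [[2, 3], [4, 6]]],
    )
    def test_small_tables_match_oracle(self, table):
        (a, b), (c, d) = table
        assert fisher_exact(ContingencyMatrix(a, b, c, d)) == pytest.approx(
            fisher_oracle(table), abs=1e-10
        )


class TestPermutationNull:
    def test_no_buoe_degs_gives_p_one(self):
        space = make_de_table(UNIVERSE, {"g0": 1})
        buoe = make_de_table(UNIVERSE, {})
        result = permutation_null(space, buoe, B=100, seed=0)
        assert result.observed_opposite == 0
        assert (result.null_counts == 0).all()
        assert result.empirical_p == 1.0
        assert (result.N_up, result.N_down) == (0, 0)

    def test_block_sizes_preserved_in_every_iteration(self):
        # every gene is a space-up DEG, so each iteration's opposite count is
        # exactly the size of the pseudo-down block: N_down, always.
        space = make_de_table(UNIVERSE, {g: 1 for g in UNIVERSE})
        buoe = make_de_table(UNIVERSE, {"g0": 1, "g1": 1, "g2": -1, "g3": -1, "g4": -1})
        result = permutation_null(space, buoe, B=200, seed=1)
        assert (result.N_up, result.N_down) == (2, 3)
        assert (result.null_counts == 3).all()
        # symmetric check with all-down space DEGs: count = N_up always
        space_down = make_de_table(UNIVERSE, {g: -1 for g in UNIVERSE})
        result = permutation_null(space_down, buoe, B=200, seed=1)
        assert (result.null_counts == 2).all()

    def test_observed_exceeding_all_null_gives_floor_p(self):
        universe = [f"g{i}" for i in range(2000)]
        degs = {f"g{i}": 1 for i in range(40)}
        opposite = {f"g{i}": -1 for i in range(40)}
        result = permutation_null(
            make_de_table(universe, degs), make_de_table(universe, opposite), B=1000, seed=2
        )
        assert result.observed_opposite == 40
        assert result.null_counts.max() < 40
        assert result.empirical_p == pytest.approx(1 / 1001)

    def test_same_seed_identical_null_counts(self):
        space = make_de_table(UNIVERSE, {"g0": 1, "g1": -1, "g2": 1})
        buoe = make_de_table(UNIVERSE, {"g2": -1, "g5": 1, "g7": -1})
        r1 = permutation_null(space, buoe, B=300, seed=9)
        r2 = permutation_null(space, buoe, B=300, seed=9)
        np.testing.assert_array_equal(r1.null_counts, r2.null_counts)
        assert r1.empirical_p == r2.empirical_p

    def test_null_mean_matches_closed_form(self):
        universe = [f"g{i}" for i in range(500)]
        space = {f"g{i}": (1 if i % 2 else -1) for i in range(0, 60)}
        buoe = {f"g{i}": (1 if i < 250 else -1) for i in range(200, 300)}
        result = permutation_null(
            make_de_table(universe, space), make_de_table(universe, buoe), B=4000, seed=3
        )
        expected = expected_null_opposite(
            n_space_up=30, n_space_down=30, n_up=result.N_up, n_down=result.N_down,
            universe_size=500,
        )
        # Monte-Carlo SE of the mean of 4000 draws
        se = result.null_counts.std() / np.sqrt(4000)
        assert abs(result.null_counts.mean() - expected) < 4 * se + 1e-9
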