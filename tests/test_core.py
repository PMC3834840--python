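"""Unit and property tests for the DIDS score, exact p-value and ranking."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dids import core
from dids.core import (
    Direction,
    GeneVector,
    SCORING_FUNCTIONS,
    analyze_gene,
    control_threshold,
    dids_bulk_scores,
    dids_score,
    exact_pvalue,
    excess_expression,
    rank_candidates,
    run_dids,
)
from dids.io import ExpressionMatrix, GroupLabels


def enumerated_pvalue(k: int, n1: int, n2: int) -> float:
    """Brute-force oracle: enumerate every assignment of n1 control and n2
    case labels to n1+n2 distinct values and count those with >= k case
    labels above the control maximum."""
    n = n1 + n2
    values = list(range(n))
    hits = total = 0
    for case_idx in itertools.combinations(range(n), n2):
        case_set = set(case_idx)
        ctrl_max = max(v for i, v in enumerate(values) if i not in case_set)
        outliers = sum(1 for i in case_idx if values[i] > ctrl_max)
        hits += outliers >= k
        total += 1
    return hits / total


class TestThresholdAndExcess:
    @pytest.mark.parametrize(
        "controls, direction, expected",
        [([1.0, 3.0, 2.0], "up", 3.0), ([1.0, 3.0, 2.0], "down", 1.0), ([5.0], "up", 5.0)],
    )
    def test_threshold_is_control_extremum(self, controls, direction, expected):
        g = GeneVector("g", controls, [0.0])
        assert control_threshold(g, direction) == expected

    @pytest.mark.parametrize(
        "cases, threshold, direction, expected",
        [
            ([0.5, 3.5, 7.0], 3.0, "up", [0.5, 4.0]),
            ([2.9, 3.0], 3.0, "up", []),  # equality is not an outlier
            ([2.0, 0.0], 1.0, "down", [1.0]),
        ],
    )
    def test_excess_is_strict_distance_beyond_threshold(self, cases, threshold, direction, expected):
        g = GeneVector("g", [threshold], cases)
        np.testing.assert_allclose(excess_expression(g, threshold, direction), expected)

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            GeneVector("g", [], [1.0])
        with pytest.raises(ValueError, match="non-empty"):
            GeneVector("g", [1.0], [])

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            GeneVector("g", [1.0, np.nan], [1.0])


class TestScore:
    @pytest.mark.parametrize(
        "excess, f, expected",
        [
            ([], "tanh", 0.0),
            ([], "quad", 0.0),
            ([1.0, 4.0], "quad", 17.0),
            ([4.0], "sqrt", 2.0),
            ([1.0, 100.0], "tanh", math.tanh(1.0) + math.tanh(100.0)),  # ~1.7616
        ],
    )
    def test_score_sums_transformed_excess(self, excess, f, expected):
        assert dids_score(excess, f) == pytest.approx(expected, abs=1e-12)

    def test_negative_excess_is_a_bug(self):
        with pytest.raises(ValueError, match="negative excess"):
            dids_score([1.0, -0.1], "tanh")

    def test_unknown_scoring_function(self):
        with pytest.raises(ValueError, match="unknown scoring"):
            dids_score([1.0], "cubic")

    @given(
        x=st.floats(min_value=0.0, max_value=50.0),
        y=st.floats(min_value=0.0, max_value=50.0),
        name=st.sampled_from(sorted(SCORING_FUNCTIONS)),
    )
    def test_scoring_functions_strictly_increase(self, x, y, name):
        f = SCORING_FUNCTIONS[name]
        assert f.apply(np.array(0.0)) == 0.0
        if x < y:
            fx, fy = f.apply(np.array(x)), f.apply(np.array(y))
            assert fx <= fy
            # strictness holds wherever f is not saturated in float64
            # (tanh rounds to 1.0 beyond ~18.7)
            if name != "tanh" or y < 18.0:
                assert fx < fy


class TestExactPvalue:
    @pytest.mark.parametrize(
        "k, n1, n2, expected",
        [
            (0, 10, 10, 1.0),
            (1, 1, 1, 0.5),
            (2, 2, 2, 1.0 / 6.0),
            (3, 5, 5, 1.0 / 12.0),  # (5/10)(4/9)(3/8)
        ],
    )
    def test_known_values(self, k, n1, n2, expected):
        assert exact_pvalue(k, n1, n2) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("n1", range(1, 7))
    @pytest.mark.parametrize("n2", range(1, 7))
    def test_matches_enumeration_oracle(self, n1, n2):
        for k in range(n2 + 1):
            assert exact_pvalue(k, n1, n2) == pytest.approx(
                enumerated_pvalue(k, n1, n2), abs=1e-12
            )

    def test_strictly_decreasing_in_k(self):
        for n1, n2 in [(3, 4), (10, 10), (25, 95)]:
            ps = [exact_pvalue(k, n1, n2) for k in range(n2 + 1)]
            assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_strictly_decreasing_in_n1(self):
        # more controls raise the bar for case outliers: P(K>=1) = n2/(n1+n2)
        for k, n2 in [(1, 5), (3, 10)]:
            ps = [exact_pvalue(k, n1, n2) for n1 in range(1, 30)]
            assert all(a > b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("k, n1, n2", [(-1, 3, 3), (4, 3, 3), (1, 0, 3), (1, 3, 0)])
    def test_domain_errors(self, k, n1, n2):
        with pytest.raises(ValueError):
            exact_pvalue(k, n1, n2)


# realistic log-expression scale on a 1e-3 grid, so value ordering (and hence
# k) cannot be flipped by float rounding under exact-invariance checks
finite_floats = st.integers(min_value=-100_000, max_value=100_000).map(
    lambda v: v / 1000.0
)


def gene_vectors(min_size=1, max_size=12):
    return st.builds(
        lambda c, b: GeneVector("g", c, b),
        st.lists(finite_floats, min_size=min_size, max_size=max_size),
        st.lists(finite_floats, min_size=min_size, max_size=max_size),
    )


class TestAnalyzeGene:
    def test_hand_composed_example(self):
        g = GeneVector("g", [0.0, 0.5, 1.0], [0.9, 2.0, 3.0])
        r = analyze_gene(g, "quad", alpha=0.05, direction="up")
        assert r.k == 2
        assert r.score == pytest.approx(5.0)  # (2-1)^2 + (3-1)^2
        assert r.p_value == pytest.approx(0.2)  # (3/6)(2/5)
        assert not r.passed_filter

    def test_singleton_groups(self):
        r = analyze_gene(GeneVector("g", [0.0], [1.0]), alpha=1.0)
        assert (r.k, r.p_value, r.passed_filter) == (1, 0.5, True)

    def test_no_outliers_means_zero_score_unit_p(self):
        g = GeneVector("g", [0.0, 2.0], [1.0, -3.0, 2.0])  # tie at threshold
        r = analyze_gene(g, "tanh", alpha=0.05)
        assert (r.k, r.score, r.p_value, r.passed_filter) == (0, 0.0, 1.0, False)

    @given(g=gene_vectors(), shift=finite_floats)
    def test_shift_invariance(self, g, shift):
        base = analyze_gene(g)
        moved = analyze_gene(GeneVector("g", g.controls + shift, g.cases + shift))
        assert base.k == moved.k
        assert base.p_value == moved.p_value
        assert base.score == pytest.approx(moved.score, rel=1e-9, abs=1e-9)

    @given(g=gene_vectors(), d=st.sampled_from(["up", "down"]))
    def test_up_down_duality(self, g, d):
        other = Direction.DOWN if Direction.coerce(d) is Direction.UP else Direction.UP
        a = analyze_gene(g, direction=d)
        b = analyze_gene(GeneVector("g", -g.controls, -g.cases), direction=other)
        assert (a.k, a.p_value) == (b.k, b.p_value)
        assert a.score == pytest.approx(b.score, abs=1e-12)
        assert a.threshold == pytest.approx(-b.threshold, abs=1e-12)

    def test_score_count_coupling(self, rng):
        for _ in range(50):
            g = GeneVector("g", rng.normal(size=8), rng.normal(size=8))
            r = analyze_gene(g)
            assert (r.score > 0) == (r.k >= 1) == (r.p_value < 1.0)

    def test_raising_existing_outlier_increases_score_only(self):
        g = GeneVector("g", [0.0, 1.0], [2.0, 0.5])
        base = analyze_gene(g, "tanh")
        bumped = analyze_gene(GeneVector("g", [0.0, 1.0], [3.0, 0.5]), "tanh")
        assert bumped.score > base.score
        assert (bumped.k, bumped.p_value) == (base.k, base.p_value)

    def test_crossing_threshold_increments_k_and_drops_p(self):
        g = GeneVector("g", [0.0, 1.0], [2.0, 0.5])
        base = analyze_gene(g, "tanh")
        crossed = analyze_gene(GeneVector("g", [0.0, 1.0], [2.0, 1.5]), "tanh")
        assert crossed.k == base.k + 1
        assert crossed.p_value < base.p_value

    def test_alpha_domain(self):
        g = GeneVector("g", [0.0], [1.0])
        with pytest.raises(ValueError):
            analyze_gene(g, alpha=0.0)


def _result(gene_id, score, p, passed, direction=Direction.UP):
    return core.GeneResult(
        gene_id=gene_id, direction=direction, n1=3, n2=3, threshold=0.0,
        k=1, score=score, p_value=p, passed_filter=passed,
    )


class TestRanking:
    def test_only_survivors_are_ranked_by_score(self):
        results = rank_candidates(
            [_result("a", 5.0, 0.01, True), _result("b", 2.0, 0.01, True),
             _result("c", 9.0, 0.5, False)]
        )
        assert [r.rank for r in results] == [1, 2, None]

    def test_empty_input(self):
        assert rank_candidates([]) == []

    def test_tie_breaks_on_p_then_gene_id(self):
        results = rank_candidates(
            [_result("z", 3.0, 0.01, True), _result("a", 3.0, 0.001, True),
             _result("b", 3.0, 0.01, True)]
        )
        by_id = {r.gene_id: r.rank for r in results}
        assert by_id == {"a": 1, "b": 2, "z": 3}

    def test_mixed_directions_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            rank_candidates(
                [_result("a", 1.0, 0.5, True), _result("b", 1.0, 0.5, True, Direction.DOWN)]
            )

    def test_ranks_are_a_permutation(self, rng):
        results = rank_candidates(
            [_result(f"g{i}", float(rng.exponential()), float(rng.uniform()), bool(i % 2))
             for i in range(40)]
        )
        ranks = sorted(r.rank for r in results if r.rank is not None)
        assert ranks == list(range(1, len(ranks) + 1))
        assert all(r.rank is None for r in results if not r.passed_filter)


def _toy_matrix(values, n1, n2):
    n_genes = len(values)
    samples = [f"c{i}" for i in range(n1)] + [f"t{i}" for i in range(n2)]
    matrix = ExpressionMatrix([f"g{i}" for i in range(n_genes)], samples, np.asarray(values))
    labels = GroupLabels({**{f"c{i}": "control" for i in range(n1)},
                          **{f"t{i}": "case" for i in range(n2)}})
    return matrix, labels


class TestRunDids:
    def test_single_gene_composition(self):
        matrix, labels = _toy_matrix([[0.0, 1.0, 2.0, 3.0]], 2, 2)
        tables = run_dids(matrix, labels, directions=["up"], alpha=0.2)
        row = tables["up"].iloc[0]
        assert row["k"] == 2
        assert row["p_value"] == pytest.approx(1.0 / 6.0)
        assert row["passed_filter"]
        assert row["rank"] == 1

    def test_negation_swaps_directions(self, rng):
        values = rng.normal(size=(30, 10))
        matrix, labels = _toy_matrix(values, 5, 5)
        neg_matrix, _ = _toy_matrix(-values, 5, 5)
        t = run_dids(matrix, labels)
        tn = run_dids(neg_matrix, labels)
        for a, b in [("up", "down"), ("down", "up")]:
            left = t[a].drop(columns=["direction", "threshold"])
            right = tn[b].drop(columns=["direction", "threshold"])
            pd_testing_assert = __import__("pandas").testing.assert_frame_equal
            pd_testing_assert(left.reset_index(drop=True), right.reset_index(drop=True))

    def test_constant_shift_leaves_tables_unchanged(self, rng):
        values = rng.normal(size=(20, 12))
        matrix, labels = _toy_matrix(values, 6, 6)
        shifted, _ = _toy_matrix(values + 17.5, 6, 6)
        t0 = run_dids(matrix, labels)
        t1 = run_dids(shifted, labels)
        for d in ("up", "down"):
            np.testing.assert_allclose(t0[d]["score"], t1[d]["score"], atol=1e-9)
            assert t0[d]["gene_id"].tolist() == t1[d]["gene_id"].tolist()
            np.testing.assert_array_equal(t0[d]["k"], t1[d]["k"])

    def test_bonferroni_is_informational_only(self, rng):
        values = rng.normal(size=(50, 8))
        matrix, labels = _toy_matrix(values, 4, 4)
        table = run_dids(matrix, labels, directions=["up"], alpha=1.0)["up"]
        np.testing.assert_allclose(
            table["p_bonferroni"], np.minimum(1.0, table["p_value"] * 50)
        )
        # ranking ignores the adjusted column: survivors sorted by raw score
        ranked = table.dropna(subset=["rank"]).sort_values("rank")
        assert (ranked["score"].diff().dropna() <= 1e-12).all()

    def test_zero_gene_matrix_rejected(self):
        matrix = ExpressionMatrix([], ["a", "b"], np.empty((0, 2)))
        labels = GroupLabels({"a": "control", "b": "case"})
        with pytest.raises(ValueError, match="no genes"):
            run_dids(matrix, labels)

    def test_unlabeled_sample_rejected(self):
        matrix, _ = _toy_matrix([[0.0, 1.0, 2.0]], 2, 1)
        labels = GroupLabels({"c0": "control", "t0": "case"})
        with pytest.raises(ValueError, match="without a group label"):
            run_dids(matrix, labels)


class TestBulkScores:
    def test_bulk_matches_per_gene_path(self, rng):
        controls = rng.normal(size=(200, 7))
        cases = rng.normal(size=(200, 9)) + 0.4
        for name in SCORING_FUNCTIONS:
            for direction in ("up", "down"):
                scores, k = dids_bulk_scores(controls, cases, name, direction)
                for i in range(0, 200, 17):
                    r = analyze_gene(GeneVector("g", controls[i], cases[i]), name,
                                     direction=direction)
                    assert scores[i] == pytest.approx(r.score, abs=1e-12)
                    assert k[i] == r.k
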