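"""Node/edge statistics: fold changes, tests, FDR, correlation changes."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from linexnet import (
    AbundanceTable,
    ChangeCategory,
    CorrelationMethod,
    TestMethod,
    annotate_network,
    build_network,
    classify_edge_change,
    differential_test,
    group_correlations,
    log_fold_change,
)
from linexnet.differential_stats import _bh_adjust
from linexnet.fixtures import (
    CorrelationBlock,
    SyntheticSpec,
    generate_abundances,
    generate_lipidome,
    parse_lipidome,
)


def make_table(values, groups, lipids=None):
    lipids = lipids or [f"L{i}" for i in range(values.shape[1])]
    samples = [f"s{i}" for i in range(values.shape[0])]
    return AbundanceTable(
        data=pd.DataFrame(values, index=samples, columns=lipids),
        groups=pd.Series(groups, index=samples),
    )


class TestLogFoldChange:
    def test_constant_groups(self):
        values = np.vstack([np.full((3, 2), 3.0), np.full((3, 2), 1.0)])
        table = make_table(values, ["A"] * 3 + ["B"] * 3)
        assert log_fold_change(table, "A", "B").tolist() == [2.0, 2.0]

    def test_identical_means_give_zero(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=(4, 3))
        table = make_table(np.vstack([half, half]), ["A"] * 4 + ["B"] * 4)
        assert np.allclose(log_fold_change(table, "A", "B"), 0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.normal(size=(10, 4)), ["A"] * 5 + ["B"] * 5)
        ab = log_fold_change(table, "A", "B")
        ba = log_fold_change(table, "B", "A")
        assert np.allclose(ab, -ba)

    def test_unknown_group_raises(self):
        table = make_table(np.zeros((4, 2)), ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="valid groups"):
            log_fold_change(table, "A", "C")


class TestBenjaminiHochberg:
    def test_worked_vector(self):
        p = pd.Series([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(_bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_missing_excluded_from_family(self):
        p = pd.Series([0.01, np.nan, 0.04])
        fdr = _bh_adjust(p)
        assert math.isnan(fdr[1])
        # family size 2, not 3
        assert fdr[0] == pytest.approx(0.02)
        assert fdr[2] == pytest.approx(0.04)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    def test_monotone_in_p_rank_and_bounded(self, p_list):
        p = pd.Series(p_list)
        fdr = _bh_adjust(p)
        assert (fdr >= p - 1e-12).all()
        assert (fdr <= 1.0 + 1e-12).all()
        order = p.sort_values().index
        assert fdr[order].is_monotonic_increasing


class TestDifferentialTest:
    def test_zero_variance_flagged_missing(self):
        values = np.column_stack(
            [np.ones(8), np.r_[np.zeros(4), np.ones(4)] + np.arange(8) * 0.1]
        )
        table = make_table(values, ["A"] * 4 + ["B"] * 4)
        result = differential_test(table, "A", "B", TestMethod.T_TEST)
        assert math.isnan(result["p_value"].iloc[0])
        assert not math.isnan(result["p_value"].iloc[1])

    def test_planted_shift_dominates_fdr_ranking(self):
        lipids = generate_lipidome(SyntheticSpec(seed=23))
        shifted = tuple(
            pd.Index(parse_lipidome(lipids)).map(lambda s: s.raw_name)[:5]
        )
        from linexnet import canonical_name, parse_lipid_name, default_ruleset

        registry = default_ruleset().registry
        shifted_canon = tuple(
            canonical_name(parse_lipid_name(n, registry)) for n in shifted
        )
        spec = SyntheticSpec(
            seed=23, n_samples_per_group=20, shifted_lipids=shifted_canon
        )
        table = generate_abundances(lipids, spec)
        result = differential_test(table, "A", "B", TestMethod.T_TEST)
        top = set(result["fdr"].nsmallest(len(shifted_canon)).index)
        assert top == set(shifted_canon)

    def test_rank_and_t_agree_on_strong_effect(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(40, 1))
        values[20:, 0] += 3.0
        table = make_table(values, ["A"] * 20 + ["B"] * 20)
        for method in (TestMethod.T_TEST, TestMethod.RANK_TEST):
            result = differential_test(table, "A", "B", method)
            assert result["fdr"].iloc[0] < 0.001

    def test_paired_signed_rank(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(10, 1))
        values = np.vstack([base, base + 1.0 + 0.01 * rng.normal(size=(10, 1))])
        table = make_table(values, ["A"] * 10 + ["B"] * 10)
        result = differential_test(
            table, "A", "B", TestMethod.RANK_TEST, paired=True
        )
        assert result["p_value"].iloc[0] < 0.01


class TestGroupCorrelations:
    def test_duplicated_lipid_has_unit_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        values = np.column_stack([x, x, rng.normal(size=20)])
        table = make_table(values, ["A"] * 20)
        result = group_correlations(table, "A")
        assert result.loc[("L0", "L1"), "r"] == pytest.approx(1.0)

    def test_two_variable_partial_equals_full(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=200)
        values = np.column_stack([z + rng.normal(size=200), z])
        table = make_table(values, ["A"] * 200)
        full = group_correlations(table, "A", partial=False)
        part = group_correlations(table, "A", partial=True)
        # shrinkage slightly attenuates; agreement is approximate
        assert part.loc[("L0", "L1"), "r"] == pytest.approx(
            full.loc[("L0", "L1"), "r"], abs=0.05
        )
        assert part.attrs["approximate"] is True

    def test_partial_removes_common_driver(self):
        # x <- z -> y: full r(x,y) large, partial r(x,y | z) near zero
        rng = np.random.default_rng(4)
        z = rng.normal(size=200)
        x = z + 0.5 * rng.normal(size=200)
        y = z + 0.5 * rng.normal(size=200)
        table = make_table(np.column_stack([x, y, z]), ["A"] * 200)
        full = group_correlations(table, "A")
        part = group_correlations(table, "A", partial=True)
        assert full.loc[("L0", "L1"), "r"] > 0.6
        assert abs(part.loc[("L0", "L1"), "r"]) < 0.25

    def test_constant_lipid_flagged_missing(self):
        rng = np.random.default_rng(7)
        values = np.column_stack([np.ones(10), rng.normal(size=10)])
        table = make_table(values, ["A"] * 10)
        result = group_correlations(table, "A")
        assert math.isnan(result.loc[("L0", "L1"), "r"])

    def test_spearman_matches_ranked_pearson(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        values = np.column_stack([x, np.exp(x)])  # monotone transform
        table = make_table(values, ["A"] * 30)
        result = group_correlations(table, "A", method=CorrelationMethod.SPEARMAN)
        assert result.loc[("L0", "L1"), "r"] == pytest.approx(1.0)


class TestClassifyEdgeChange:
    @pytest.mark.parametrize(
        "r1, fdr1, r2, fdr2, expected",
        [
            (0.3, 0.4, 0.5, 0.01, ChangeCategory.TURNED_SIGNIFICANT),
            (0.1, 0.9, -0.1, 0.8, ChangeCategory.UNCHANGED_INSIGNIFICANT),
            (0.5, 0.01, 0.3, 0.4, ChangeCategory.TURNED_INSIGNIFICANT),
            (0.5, 0.01, 0.6, 0.02, ChangeCategory.UNCHANGED_SIGNIFICANT),
            (0.5, 0.01, -0.6, 0.02, ChangeCategory.SIGN_CHANGE),
            # a sign flip with one side insignificant is a turned category
            (0.5, 0.01, -0.6, 0.5, ChangeCategory.TURNED_INSIGNIFICANT),
        ],
    )
    def test_examples(self, r1, fdr1, r2, fdr2, expected):
        assert classify_edge_change(r1, fdr1, r2, fdr2, 0.05) is expected

    def test_exhaustive_grid_yields_exactly_five_categories(self):
        """All (sig1, sig2, sign-agreement) cells collapse to 5 categories."""
        seen = set()
        for sig1, sig2, same_sign in itertools.product([False, True], repeat=3):
            fdr1 = 0.01 if sig1 else 0.5
            fdr2 = 0.01 if sig2 else 0.5
            r1, r2 = 0.5, (0.5 if same_sign else -0.5)
            seen.add(classify_edge_change(r1, fdr1, r2, fdr2, 0.05))
        assert seen == set(ChangeCategory)

    def test_boundary_fdr_equal_alpha_is_insignificant(self):
        assert (
            classify_edge_change(0.5, 0.05, 0.5, 0.01, 0.05)
            is ChangeCategory.TURNED_SIGNIFICANT
        )
        assert (
            classify_edge_change(0.5, 0.05, 0.5, 0.05, 0.05)
            is ChangeCategory.UNCHANGED_INSIGNIFICANT
        )

    def test_missing_inputs_flagged(self):
        assert classify_edge_change(float("nan"), 0.01, 0.5, 0.01) is None
        assert classify_edge_change(0.5, 0.01, 0.5, None) is None

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(-1, 1), st.floats(0, 1), st.floats(-1, 1), st.floats(0, 1),
    )
    def test_every_finite_input_maps_to_one_category(self, r1, fdr1, r2, fdr2):
        category = classify_edge_change(r1, fdr1, r2, fdr2, 0.05)
        assert isinstance(category, ChangeCategory)

    def test_antisymmetry_under_group_swap(self):
        cases = [
            (0.3, 0.4, 0.5, 0.01),
            (0.5, 0.01, 0.3, 0.4),
            (0.5, 0.01, -0.6, 0.02),
            (0.5, 0.01, 0.6, 0.02),
            (0.1, 0.9, -0.1, 0.8),
        ]
        swap = {
            ChangeCategory.TURNED_SIGNIFICANT: ChangeCategory.TURNED_INSIGNIFICANT,
            ChangeCategory.TURNED_INSIGNIFICANT: ChangeCategory.TURNED_SIGNIFICANT,
        }
        for r1, fdr1, r2, fdr2 in cases:
            forward = classify_edge_change(r1, fdr1, r2, fdr2)
            backward = classify_edge_change(r2, fdr2, r1, fdr1)
            assert backward is swap.get(forward, forward)


class TestAnnotateNetwork:
    def _small_setup(self, seed=31, **spec_kw):
        spec = SyntheticSpec(seed=seed, **spec_kw)
        lipids = generate_lipidome(spec)
        table = generate_abundances(lipids, spec)
        from linexnet import default_ruleset

        rules = default_ruleset()
        net = build_network(parse_lipidome(lipids, rules), rules)
        return net, table

    def test_attributes_attached_per_comparison(self):
        net, table = self._small_setup()
        annotate_network(net, table, [("A", "B")])
        node = next(iter(net.nodes))
        for key in (
            "log_fold_change_A_vs_B", "p_value_A_vs_B", "fdr_A_vs_B",
            "degree", "betweenness", "closeness",
        ):
            assert key in net.nodes[node]
        for u, v in net.edges:
            assert "r_A" in net.edges[u, v]
            assert "change_A_vs_B" in net.edges[u, v]

    def test_multiple_comparisons_coexist(self):
        spec = SyntheticSpec(seed=37, group_labels=("A", "B", "C"))
        lipids = generate_lipidome(spec)
        table = generate_abundances(lipids, spec)
        from linexnet import default_ruleset

        rules = default_ruleset()
        net = build_network(parse_lipidome(lipids, rules), rules)
        annotate_network(net, table, [("A", "B"), ("B", "C")])
        node = next(iter(net.nodes))
        assert "log_fold_change_A_vs_B" in net.nodes[node]
        assert "log_fold_change_B_vs_C" in net.nodes[node]

    def test_unknown_group_raises(self):
        net, table = self._small_setup()
        with pytest.raises(ValueError, match="valid groups"):
            annotate_network(net, table, [("A", "X")])

    def test_reannotation_overwrites(self):
        net, table = self._small_setup()
        annotate_network(net, table, [("A", "B")])
        first = dict(net.nodes[next(iter(net.nodes))])
        annotate_network(net, table, [("A", "B")])
        second = dict(net.nodes[next(iter(net.nodes))])
        assert first == second

    def test_annotation_survives_edge_filtering(self):
        from linexnet import ReactionType, filter_edges

        net, table = self._small_setup()
        annotate_network(net, table, [("A", "B")])
        kept = filter_edges(net, {ReactionType.CLASS_CONVERSION})
        node = next(iter(kept.nodes))
        assert "log_fold_change_A_vs_B" in kept.nodes[node]
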