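import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcenet.datatypes import CorrelationMatrix, IndividualCorrelationStack, NetworkParams
from dcenet.coexpression import (
    build_network,
    frobenius_distance,
    group_mean_correlation,
    individual_correlations,
    individual_distance_profile,
)

from _reference import reference_frobenius, reference_network_edges
from conftest import make_expr, make_samplesheet, random_stack


def stack_from_series(series_by_gene, group="G"):
    """One group, individuals inferred from the series length lists."""
    genes = list(series_by_gene)
    n_ind = len(next(iter(series_by_gene.values())))
    samples = make_samplesheet({group: n_ind})
    values = np.array(
        [[x for ind_series in series_by_gene[g] for x in ind_series] for g in genes],
        dtype=float,
    )
    expr = make_expr(values, genes, samples)
    return individual_correlations(expr, genes, group)


class TestIndividualCorrelations:
    def test_perfect_anticorrelation(self):
        stack = stack_from_series({"x": [(1, 2, 3)], "y": [(6, 4, 2)]})
        assert stack.matrices["G01"][0, 1] == pytest.approx(-1.0)

    def test_zero_variance_gives_nan(self):
        stack = stack_from_series({"x": [(1, 2, 3)], "y": [(5, 5, 5)]})
        m = stack.matrices["G01"]
        assert math.isnan(m[0, 1])
        assert m[0, 0] == 1.0 and math.isnan(m[1, 1])

    def test_hand_computed_pearson(self):
        stack = stack_from_series({"x": [(1, 2, 3)], "y": [(1, 2, 10)]})
        expected = 9 / (math.sqrt(2) * math.sqrt(438 / 9))
        assert stack.matrices["G01"][0, 1] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.9122, abs=5e-5)

    def test_incomplete_series_is_error(self):
        samples = make_samplesheet({"G": 2})
        expr = make_expr(np.ones((2, 6)), ["a", "b"], samples)
        sub = [c for c in expr.sample_ids if c != "G02_T3"]
        from dcenet.datatypes import ExpressionMatrix
        broken = ExpressionMatrix(expr.values[sub], expr.samples.loc[sub])
        with pytest.raises(ValueError, match="incomplete"):
            individual_correlations(broken, ["a", "b"], "G")

    def test_fewer_than_two_genes_is_error(self, toy_expr):
        with pytest.raises(ValueError, match="at least 2"):
            individual_correlations(toy_expr, ["g1"], "LCD")

    def test_matrices_are_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(2)
        samples = make_samplesheet({"G": 4})
        expr = make_expr(rng.normal(5, 1, (6, 12)), [f"g{i}" for i in range(6)], samples)
        stack = individual_correlations(expr, expr.gene_ids, "G")
        for m in stack.matrices.values():
            assert np.array_equal(m, m.T, equal_nan=True)
            assert np.allclose(np.diag(m), 1.0)
            assert np.nanmax(np.abs(m)) <= 1.0


def stack_from_pair_correlations(r_values):
    """Two-gene stack with a prescribed correlation per individual."""
    genes = ["a", "b"]
    mats = {}
    for k, r in enumerate(r_values):
        m = np.array([[1.0, r], [r, 1.0]])
        mats[f"ind{k:02d}"] = m
    return IndividualCorrelationStack(gene_ids=genes, matrices=mats)


class TestBuildNetwork:
    def test_hand_example_support_and_weight(self):
        stack = stack_from_pair_correlations([0.9, 0.65, 0.1, -0.3])
        net = build_network(stack, NetworkParams(0.6, 0.25))
        assert net.n_edges == 1
        edge = net.edges.iloc[0]
        assert (edge["source"], edge["target"]) == ("a", "b")
        assert edge["support"] == pytest.approx(0.5)
        assert edge["weight"] == pytest.approx(0.775)
        assert edge["sign"] == "+"

    def test_no_individual_passes_cutoff(self):
        stack = stack_from_pair_correlations([0.5, 0.5, 0.5, 0.5])
        assert build_network(stack, NetworkParams(0.6, 0.25)).n_edges == 0

    def test_conflicting_qualifying_signs_rejected(self):
        stack = stack_from_pair_correlations([0.9, -0.9, 0.0, 0.0])
        assert build_network(stack, NetworkParams(0.6, 0.25)).n_edges == 0

    def test_nan_correlations_count_against_support(self):
        # 2 qualifiers of 8 individuals -> support 0.25 passes; NaNs don't qualify
        stack = stack_from_pair_correlations([0.9, 0.8] + [np.nan] * 6)
        net = build_network(stack, NetworkParams(0.6, 0.25))
        assert net.n_edges == 1
        assert net.edges.iloc[0]["support"] == pytest.approx(0.25)
        # but 2 of 9 falls below the fraction
        stack9 = stack_from_pair_correlations([0.9, 0.8] + [np.nan] * 7)
        assert build_network(stack9, NetworkParams(0.6, 0.25)).n_edges == 0

    def test_weight_magnitude_at_least_cutoff(self):
        rng = np.random.default_rng(3)
        stack = random_stack(rng, 12, 8, nan_frac=0.1)
        net = build_network(stack, NetworkParams(0.6, 0.25))
        if net.n_edges:
            assert (net.edges["weight"].abs() >= 0.6).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triple_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        stack = random_stack(rng, rng.integers(3, 15), rng.integers(2, 9), nan_frac=0.15)
        params = NetworkParams(0.6, 0.25)
        net = build_network(stack, params)
        assert net.edge_set() == reference_network_edges(stack, 0.6, 0.25)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_monotone_in_support_and_in_cutoff_for_consistent_pairs(self, seed):
        """Raising the support fraction never adds an edge. Raising the
        cutoff never adds an edge either, except for pairs whose qualifying
        correlations conflicted in sign at the looser cutoff (dropping the
        conflicting qualifier can newly admit the pair)."""
        rng = np.random.default_rng(seed)
        stack = random_stack(rng, 8, 6, nan_frac=0.1)
        base = build_network(stack, NetworkParams(0.5, 0.2)).edge_set()
        tighter_cut = build_network(stack, NetworkParams(0.7, 0.2)).edge_set()
        tighter_sup = build_network(stack, NetworkParams(0.5, 0.5)).edge_set()
        assert tighter_sup <= base

        genes = stack.gene_ids
        conflicted = set()
        R = stack.as_array()
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                rs = R[:, i, j]
                qual = rs[~np.isnan(rs)]
                qual = qual[np.abs(qual) >= 0.5]
                if len(qual) and (qual > 0).any() and (qual < 0).any():
                    conflicted.add(tuple(sorted((genes[i], genes[j]))))
        assert tighter_cut - conflicted <= base


class TestGroupMean:
    def test_mean_of_two(self):
        stack = stack_from_pair_correlations([0.8, 0.4])
        mean = group_mean_correlation(stack)
        assert mean.values[0, 1] == pytest.approx(0.6)

    def test_nan_aware_mean(self):
        stack = stack_from_pair_correlations([np.nan, 0.5])
        assert group_mean_correlation(stack).values[0, 1] == pytest.approx(0.5)

    def test_single_individual_identity(self):
        stack = stack_from_pair_correlations([0.37])
        assert np.array_equal(group_mean_correlation(stack).values,
                              stack.matrices["ind00"], equal_nan=True)


class TestFrobenius:
    def _cm(self, values):
        n = values.shape[0]
        return CorrelationMatrix([f"g{i}" for i in range(n)], values)

    def test_identity_of_indiscernibles(self):
        a = self._cm(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert frobenius_distance(a, a) == 0.0

    def test_forced_two_by_two(self):
        a = self._cm(np.eye(2))
        b = self._cm(np.ones((2, 2)))
        assert frobenius_distance(a, b) == pytest.approx(math.sqrt(2))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            stack = random_stack(rng, 6, 2, nan_frac=0.1)
            a = stack.matrix_for("ind00")
            b = stack.matrix_for("ind01")
            assert frobenius_distance(a, b) == pytest.approx(
                reference_frobenius(a.values, b.values), abs=1e-12)

    def test_mismatched_gene_sets_rejected(self):
        a = self._cm(np.eye(2))
        b = CorrelationMatrix(["x", "y"], np.eye(2))
        with pytest.raises(ValueError, match="different gene sets"):
            frobenius_distance(a, b)

    def test_nan_error_policy(self):
        a = self._cm(np.array([[1.0, np.nan], [np.nan, 1.0]]))
        b = self._cm(np.eye(2))
        with pytest.raises(ValueError, match="undefined"):
            frobenius_distance(a, b, on_nan="error")

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            stack = random_stack(rng, 5, 3)
            a, b, c = (stack.matrix_for(i) for i in stack.individual_ids)
            dab = frobenius_distance(a, b)
            dba = frobenius_distance(b, a)
            dac = frobenius_distance(a, c)
            dcb = frobenius_distance(c, b)
            assert dab >= 0
            assert dab == pytest.approx(dba, abs=1e-14)
            assert dab <= dac + dcb + 1e-12


class TestDistanceProfile:
    def test_identical_individuals_have_zero_distance(self):
        stack = stack_from_pair_correlations([0.4, 0.4, 0.4])
        profile = individual_distance_profile(stack)
        assert np.allclose(profile.to_numpy(), 0.0)

    def test_mirror_pair_symmetric(self):
        stack = stack_from_pair_correlations([0.5, -0.5])
        profile = individual_distance_profile(stack)
        assert profile.iloc[0] == pytest.approx(profile.iloc[1])

    def test_matches_oracle_recomputation(self):
        rng = np.random.default_rng(6)
        stack = random_stack(rng, 6, 5, nan_frac=0.05)
        profile = individual_distance_profile(stack)
        mean = group_mean_correlation(stack)
        for ind in stack.individual_ids:
            expected = reference_frobenius(stack.matrices[ind], mean.values)
            assert profile[ind] == pytest.approx(expected, abs=1e-12)
        assert list(profile) == sorted(profile, reverse=True)

    def test_needs_two_individuals(self):
        stack = stack_from_pair_correlations([0.4])
        with pytest.raises(ValueError, match="at least 2"):
            individual_distance_profile(stack)
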