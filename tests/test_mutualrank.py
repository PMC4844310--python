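import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from graincoex.io import Atlas, ExpressionExperiment, MutualRankRecord
from graincoex.mutualrank import (
    UndefinedCorrelationError,
    bait_mr_series,
    combine_across_experiments,
    correlation_vector,
    mutual_rank,
    mutual_rank_matrix,
    mutual_rank_records,
    pearson,
    select_candidates,
)


def random_experiment(rng, n_genes, n_samples, accession="R"):
    values = pd.DataFrame(
        rng.normal(6.0, 2.0, size=(n_genes, n_samples)),
        index=[f"g{i:02d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)])
    samples = pd.DataFrame(
        {"tissue": "endosperm", "stage": "1 DAP", "stage_pos": 1.0,
         "genotype": "wt", "replicate": range(1, n_samples + 1)},
        index=values.columns)
    return ExpressionExperiment(accession, values, samples)


def brute_force_mr(values: pd.DataFrame) -> pd.DataFrame:
    """Independent oracle: explicit per-gene sorted correlation lists.

    Pearson from the textbook formula per pair; ranks assigned by walking
    the explicitly sorted list and averaging positions of exact ties.
    """
    genes = list(values.index)
    n = len(genes)
    corr = {}
    for a in genes:
        for b in genes:
            if a == b:
                continue
            x = values.loc[a].to_numpy()
            y = values.loc[b].to_numpy()
            mx, my = x.mean(), y.mean()
            num = ((x - mx) * (y - my)).sum()
            den = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
            corr[a, b] = num / den

    def ranks_from(a):
        others = [b for b in genes if b != a]
        ordered = sorted(others, key=lambda b: -corr[a, b])
        ranks = {}
        i = 0
        while i < len(ordered):
            j = i
            while (j + 1 < len(ordered)
                   and corr[a, ordered[j + 1]] == corr[a, ordered[i]]):
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[ordered[k]] = avg
            i = j + 1
        return ranks

    rank = {a: ranks_from(a) for a in genes}
    out = pd.DataFrame(np.nan, index=genes, columns=genes)
    for a in genes:
        for b in genes:
            if a != b:
                out.at[a, b] = math.sqrt(rank[a][b] * rank[b][a])
    return out


class TestPearson:
    def test_perfect_positive(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # centered cross-product 4.0 over sqrt(5*5)
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError, match="zero variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_pairwise_complete_deletion(self):
        x = [1.0, 2.0, math.nan, 3.0, 4.0]
        y = [1.0, 3.0, 9.0, 2.0, 4.0]
        assert pearson(x, y) == pytest.approx(0.8)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(UndefinedCorrelationError, match="complete pairs"):
            pearson([1.0, math.nan, 3.0], [1.0, 2.0, math.nan], min_pairs=3)


class TestCorrelationVector:
    def test_count_excludes_self(self):
        rng = np.random.default_rng(0)
        exp = random_experiment(rng, 5, 6)
        vec = correlation_vector(exp, "g00")
        assert len(vec.r) == 4
        assert "g00" not in vec.r.index

    def test_constant_gene_excluded_with_reason(self):
        rng = np.random.default_rng(0)
        exp = random_experiment(rng, 4, 6)
        exp.values.loc["g01"] = 5.0
        vec = correlation_vector(exp, "g00")
        assert "g01" not in vec.r.index
        assert "zero variance" in vec.excluded["g01"]

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(3)
        exp = random_experiment(rng, 6, 8)
        vec = correlation_vector(exp, "g02")
        for gene in vec.r.index:
            expected = pearson(exp.values.loc["g02"], exp.values.loc[gene])
            assert vec.r[gene] == pytest.approx(expected, abs=1e-12)


class TestMutualRank:
    def test_reciprocal_top_partners_give_unit_mr(self):
        # two perfectly collinear genes are each other's rank-1 partner
        values = pd.DataFrame({
            "a": [1.0, 2.0, 3.0, 4.0],
            "b": [2.0, 4.0, 6.0, 8.0],
            "c": [5.0, 1.0, 4.0, 2.0],
            "d": [1.0, 5.0, 2.0, 4.5],
        }).T
        values.columns = [f"s{i}" for i in range(4)]
        samples = pd.DataFrame(
            {"tissue": "t", "stage": "1 DAP", "stage_pos": 1.0,
             "genotype": "wt", "replicate": [1, 2, 3, 4]}, index=values.columns)
        exp = ExpressionExperiment("E", values, samples)
        assert mutual_rank(exp, "a", "b") == pytest.approx(1.0)

    def test_closed_form_from_rank_product(self):
        assert math.sqrt(4 * 9) == pytest.approx(6.0)
        rng = np.random.default_rng(11)
        exp = random_experiment(rng, 10, 8)
        mr = mutual_rank_matrix(exp)
        oracle = brute_force_mr(exp.values)
        pd.testing.assert_frame_equal(mr, oracle, atol=1e-9, rtol=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(4, 13))
        n_samples = int(rng.integers(4, 11))
        exp = random_experiment(rng, n_genes, n_samples)
        mr = mutual_rank_matrix(exp)
        oracle = brute_force_mr(exp.values)
        assert np.nanmax(np.abs(mr.to_numpy() - oracle.to_numpy())) < 1e-9

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        exp = random_experiment(rng, 12, 7)
        mr = mutual_rank_matrix(exp).to_numpy()
        assert np.allclose(mr, mr.T, equal_nan=True)
        off_diag = mr[~np.isnan(mr)]
        assert (off_diag >= 1.0).all()
        assert (off_diag <= len(exp.gene_ids) - 1).all()

    def test_affine_invariance_of_whole_matrix(self):
        rng = np.random.default_rng(9)
        exp = random_experiment(rng, 8, 6)
        shifted = ExpressionExperiment(
            "S", exp.values * 3.0 + 11.0, exp.samples)
        pd.testing.assert_frame_equal(
            mutual_rank_matrix(exp),
            mutual_rank_matrix(shifted).set_axis(exp.values.index, axis=0)
            .set_axis(exp.values.index, axis=1),
            atol=1e-9, rtol=0)

    def test_bait_series_agrees_with_full_matrix(self):
        rng = np.random.default_rng(21)
        exp = random_experiment(rng, 15, 9)
        full = mutual_rank_matrix(exp)
        series = bait_mr_series(exp, "g03")
        for gene, mr in series.items():
            assert mr == pytest.approx(full.at["g03", gene], abs=1e-12)


class TestCombine:
    def test_geometric_mean_identity_on_equal_values(self):
        assert combine_across_experiments(
            {"a": 10.0, "b": 10.0, "c": 10.0}, "geometric_mean") == pytest.approx(10.0)

    def test_geometric_mean_closed_form(self):
        assert combine_across_experiments(
            {"a": 4.0, "b": 16.0}, "geometric_mean") == pytest.approx(8.0)

    @given(st.lists(st.floats(min_value=1.0, max_value=500.0), min_size=2, max_size=6))
    @settings(derandomize=True, max_examples=50)
    def test_geometric_mean_matches_logspace_oracle(self, mrs):
        per = {f"E{i}": v for i, v in enumerate(mrs)}
        expected = math.exp(np.mean([math.log(v) for v in mrs]))
        assert combine_across_experiments(per, "geometric_mean") == pytest.approx(expected)

    @given(st.floats(min_value=1.0, max_value=500.0))
    @settings(derandomize=True, max_examples=30)
    def test_single_experiment_identity_all_policies(self, mr):
        for policy in ("geometric_mean", "max"):
            assert combine_across_experiments({"E": mr}, policy) == pytest.approx(mr)

    def test_max_policy_is_worst_case(self):
        assert combine_across_experiments({"a": 3.0, "b": 30.0}, "max") == 30.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_across_experiments({}, "max")


class TestSelectCandidates:
    def _records(self, gene_mrs):
        records = []
        for gene, mrs in gene_mrs.items():
            for bait, mr in zip(("b1", "b2", "b3"), mrs):
                records.append(MutualRankRecord(bait, gene, {"E": mr}, mr, 1))
        return records

    def test_gene_under_threshold_for_all_baits_included(self):
        cs = select_candidates(self._records({"g": (5, 12, 19)}), ["b1", "b2", "b3"], 20)
        assert "g" in cs

    def test_strict_boundary_excludes(self):
        cs = select_candidates(self._records({"g": (5, 12, 21)}), ["b1", "b2", "b3"], 20)
        assert "g" not in cs
        cs = select_candidates(self._records({"g": (5, 12, 20)}), ["b1", "b2", "b3"], 20)
        assert "g" not in cs  # strict '<'

    def test_baits_never_members(self):
        recs = self._records({"b2": (2, 1, 3), "g": (5, 5, 5)})
        cs = select_candidates(recs, ["b1", "b2", "b3"], 20)
        assert cs.gene_ids == ["g"]

    def test_sorted_by_worst_bait_mr_then_gene_id(self):
        recs = self._records({"late": (19, 19, 19), "early": (2, 3, 4),
                              "tied": (19, 18, 19)})
        cs = select_candidates(recs, ["b1", "b2", "b3"], 20)
        assert cs.gene_ids == ["early", "late", "tied"]

    @given(st.dictionaries(
        st.text(alphabet="ghij", min_size=1, max_size=3),
        st.tuples(*[st.floats(min_value=1, max_value=100)] * 3),
        max_size=12))
    @settings(derandomize=True, max_examples=50)
    def test_threshold_nesting(self, gene_mrs):
        recs = self._records(gene_mrs)
        small = select_candidates(recs, ["b1", "b2", "b3"], 20)
        large = select_candidates(recs, ["b1", "b2", "b3"], 50)
        assert set(small.gene_ids) <= set(large.gene_ids)


class TestRecordsAcrossExperiments:
    def test_coverage_requires_gene_everywhere_bait_is(self):
        rng = np.random.default_rng(2)
        e1 = random_experiment(rng, 8, 6, "E1")
        e2 = random_experiment(rng, 8, 6, "E2")
        # drop g07 from E2: it cannot meet default min_coverage for any bait
        e2 = ExpressionExperiment("E2", e2.values.drop(index="g07"), e2.samples)
        records = mutual_rank_records(Atlas([e1, e2]), ["g00"])
        by_gene = {r.gene: r for r in records}
        assert by_gene["g07"].coverage == 1
        assert math.isnan(by_gene["g07"].combined)
        assert by_gene["g05"].coverage == 2
        assert not math.isnan(by_gene["g05"].combined)
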