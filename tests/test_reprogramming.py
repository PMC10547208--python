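import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mri
from mri.reprogramming import (
    AnalysisConfig,
    adaptation_score_ratio,
    compare_usage_sets,
    identify_key_genes,
    pearson_correlation,
    run_full_analysis,
)


def _profiles(**levels_by_strain):
    return {
        strain: mri.ExpressionProfile(strain, dict(levels))
        for strain, levels in levels_by_strain.items()
    }


class TestIdentifyKeyGenes:
    def test_shifted_gene_ranks_first(self, toy1_wt):
        evolved = [
            mri.ExpressionProfile("EV1", {"g1": 2.0, "g2": 6.0, "g3": 5.0}),
            mri.ExpressionProfile("EV2", {"g1": 2.0, "g2": 6.0, "g3": 5.0}),
        ]
        table = identify_key_genes({"g1", "g2", "g3"}, toy1_wt, evolved)
        assert table.table.index[0] == "g2"
        assert table.table.at["g2", "delta_expression"] == pytest.approx(2.0)
        assert table.table.at["g2", "rank"] == 1
        assert bool(table.table.at["g2", "wt_extreme"]) is True

    def test_invariant_under_evolved_order(self, toy1_wt):
        ev1 = mri.ExpressionProfile("EV1", {"g1": 2.5, "g2": 6.0, "g3": 5.0})
        ev2 = mri.ExpressionProfile("EV2", {"g1": 2.0, "g2": 7.0, "g3": 4.0})
        a = identify_key_genes({"g1", "g2", "g3"}, toy1_wt, [ev1, ev2])
        b = identify_key_genes({"g1", "g2", "g3"}, toy1_wt, [ev2, ev1])
        assert list(a.table.index) == list(b.table.index)
        np.testing.assert_allclose(
            a.table["delta_expression"], b.table["delta_expression"]
        )

    def test_identical_profiles_select_nothing(self, toy1_wt):
        table = identify_key_genes(
            {"g1", "g2", "g3"}, toy1_wt, [toy1_wt], min_delta=0.0
        )
        assert (table.table["delta_expression"] == 0).all()
        assert table.selected_genes == []

    def test_gene_missing_from_evolved_excluded(self, toy1_wt, caplog):
        ev = mri.ExpressionProfile("EV1", {"g1": 2.0, "g3": 6.0})
        with caplog.at_level("WARNING", logger="mri.reprogramming"):
            table = identify_key_genes({"g1", "g2", "g3"}, toy1_wt, [ev])
        assert "g2" not in table.table.index
        assert len(table.table) == 2

    def test_ranks_are_a_permutation_with_deterministic_ties(self, toy1_wt):
        ev = mri.ExpressionProfile("EV1", {"g1": 3.0, "g2": 5.0, "g3": 6.0})
        # deltas: g1 -> 1, g2 -> 1, g3 -> 1; ties broken by gene id
        table = identify_key_genes({"g1", "g2", "g3"}, toy1_wt, [ev])
        assert sorted(table.table["rank"]) == [1, 2, 3]
        assert list(table.table.index) == ["g1", "g2", "g3"]

    def test_accepts_witness_result(self, toy1_wt, toy1_result):
        ev = mri.ExpressionProfile("EV1", {"g1": 2.0, "g2": 6.0, "g3": 5.0})
        table = identify_key_genes(toy1_result, toy1_wt, [ev])
        assert set(table.table.index) <= {"g1", "g2", "g3"}

    def test_requires_an_evolved_profile(self, toy1_wt):
        with pytest.raises(ValueError):
            identify_key_genes({"g1"}, toy1_wt, [])


class TestPearson:
    def test_identical_vectors_correlate_perfectly(self):
        report = pearson_correlation([1, 2, 3], [1, 2, 3])
        assert report.pearson_r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # r = 15 / sqrt(228) by the closed form
        report = pearson_correlation([1, 2, 3], [2, 4, 7])
        assert report.pearson_r == pytest.approx(15 / np.sqrt(228), abs=1e-12)
        assert report.pearson_r == pytest.approx(0.9934, abs=1e-4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_closed_form_and_t_cdf(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        report = pearson_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_closed = float(
            (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        )
        assert report.pearson_r == pytest.approx(r_closed, abs=1e-12)
        t = r_closed * np.sqrt((n - 2) / (1 - r_closed**2))
        p_indep = 2 * stats.t.sf(abs(t), df=n - 2)
        assert report.p_value == pytest.approx(p_indep, abs=1e-9)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2])


class TestUsageSetComparison:
    def test_identical_sets_all_in_core(self):
        sets = {s: {"a", "b", "c"} for s in ("WT", "E1", "E2")}
        regions = compare_usage_sets(sets)
        assert regions[frozenset({"WT", "E1", "E2"})] == 3
        assert sum(v for k, v in regions.items()
                   if k != frozenset({"WT", "E1", "E2"})) == 0

    def test_two_set_partition(self):
        regions = compare_usage_sets({"s1": {"a", "b"}, "s2": {"b", "c"}})
        assert regions[frozenset({"s1"})] == 1
        assert regions[frozenset({"s2"})] == 1
        assert regions[frozenset({"s1", "s2"})] == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_region_counts_sum_to_union(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(12)]
        k = int(rng.integers(2, 5))
        sets = {
            f"s{j}": {g for g in universe if rng.random() < 0.4}
            for j in range(k)
        }
        regions = compare_usage_sets(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_more_than_four_sets_rejected(self):
        sets = {f"s{i}": {"a"} for i in range(5)}
        with pytest.raises(ValueError, match="2-4"):
            compare_usage_sets(sets)


class TestScoreRatio:
    def _result(self, score):
        return mri.AdaptationResult(
            P=10, score=score, fully_used_genes=set(), alpha_values={},
            witness_flux={}, solver_status="optimal",
        )

    def test_equal_scores_ratio_one(self):
        assert adaptation_score_ratio(self._result(7), self._result(7)) == 1.0

    def test_arithmetic(self):
        assert adaptation_score_ratio(self._result(50), self._result(25)) == 2.0

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError):
            adaptation_score_ratio(self._result(5), self._result(0))


class TestFullAnalysis:
    def test_toy1_bundle_end_to_end(self, toy1, toy1_wt, toy1_ev, medium, tmp_path):
        config = AnalysisConfig(medium=medium, C=1.0, top_k=1)
        bundle = run_full_analysis(
            toy1, [toy1_wt, toy1_ev], None, config, out_dir=tmp_path
        )
        assert bundle["unlimited_scores"]["WT"]["score"] == 2
        assert bundle["key_genes"]["selected"] == ["g2"]
        assert "g2" in bundle["conditional_scores"]
        assert bundle["status"]["correlations"].startswith("not computed")
        assert (tmp_path / "bundle.json").exists()
        assert (tmp_path / "keygenes.tsv").exists()

    def test_correlations_computed_with_phenotypes(self, toy1, medium):
        import pandas as pd

        wt = mri.ExpressionProfile("WT", {"g1": 2.0, "g2": 4.0, "g3": 5.0})
        evs = [
            mri.ExpressionProfile(f"EV{i}", {"g1": 2.0, "g2": 4.0 + i, "g3": 5.0})
            for i in (1, 2, 3)
        ]
        phen = mri.PhenotypeTable(
            pd.DataFrame(
                {"growth_rate": [0.2, 0.5, 0.6, 0.7]},
                index=["WT", "EV1", "EV2", "EV3"],
            )
        )
        config = AnalysisConfig(medium=medium, C=1.0, top_k=1)
        bundle = run_full_analysis(toy1, [wt, *evs], phen, config)
        assert bundle["status"]["correlations"] == "ok"
        gene = bundle["key_genes"]["selected"][0]
        rep = bundle["correlations"][gene]["growth_rate"]
        assert "pearson_r" in rep or "status" in rep
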