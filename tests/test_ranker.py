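import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fibromark import (
    WeightSetting,
    assemble_subscores,
    dimension_scores,
    literature_subscore,
    load_weight_settings,
    rank_normalize,
    sensitivity_analysis,
    total_score_and_rank,
)
from fibromark.ranker import ALL_SUBSCORES, DIMENSION_SUBSCORES, DIMENSIONS


class TestWeightSettings:
    def test_packaged_file_has_six_settings_summing_to_one(self):
        settings_ = load_weight_settings()
        assert len(settings_) == 6
        names = {s.name for s in settings_}
        assert names == {
            "default", "prior_knowledge", "balanced",
            "liver_plasma_specific", "liver_specific", "plasma_specific",
        }
        for s in settings_:
            assert s.as_array().sum() == 1.0  # exact
        default = next(s for s in settings_ if s.name == "default")
        assert (default.plasma, default.liver, default.prior, default.secreted) == (
            0.3, 0.3, 0.2, 0.2,
        )

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightSetting("bad", 0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            WeightSetting("bad", -0.5, 0.5, 0.5, 0.5)


class TestRankNormalize:
    def test_basic_and_ties(self):
        np.testing.assert_allclose(rank_normalize([10, 20, 30]), [0, 0.5, 1])
        np.testing.assert_allclose(rank_normalize([5, 5]), [0.5, 0.5])
        np.testing.assert_allclose(rank_normalize([7]), [0.5])

    def test_monotone_transform_of_input(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=200)
        out = rank_normalize(v)
        assert stats.spearmanr(v, out)[0] == pytest.approx(1.0)
        assert out.min() == 0.0 and out.max() == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    def test_output_in_unit_interval_and_order_preserving(self, vals):
        out = rank_normalize(vals)
        assert ((out >= 0) & (out <= 1)).all()
        v = np.asarray(vals)
        i, j = np.argmin(v), np.argmax(v)
        assert out[i] <= out[j]

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            rank_normalize([np.nan, np.nan])
        with pytest.raises(ValueError):
            rank_normalize([1.0, np.nan])


class TestLiteratureSubscore:
    def test_all_zero_counts_tie_at_half(self):
        a, b = literature_subscore(np.zeros(5), np.ones(5))
        np.testing.assert_allclose(a, 0.5)
        np.testing.assert_allclose(b, 0.5)

    def test_counts_ranked(self):
        a, b = literature_subscore(np.array([0, 10, 100]), np.ones(3))
        np.testing.assert_allclose(a, [0, 0.5, 1])
        np.testing.assert_allclose(b, [0, 0.5, 1])

    def test_expected_counts_separate_ties(self):
        a, b = literature_subscore(np.array([10.0, 10.0]), np.array([1.0, 100.0]))
        np.testing.assert_allclose(a, [0.5, 0.5])
        np.testing.assert_allclose(b, [1.0, 0.0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            literature_subscore(np.array([-1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            literature_subscore(np.array([1.0]), np.array([0.0]))


def _subscore_frame(values: dict) -> pd.DataFrame:
    n = len(next(iter(values.values())))
    data = {c: values.get(c, np.zeros(n)) for c in ALL_SUBSCORES}
    return pd.DataFrame(data, index=[f"g{i}" for i in range(n)])


class TestDimensionScores:
    def test_all_ones_gives_ones(self):
        subs = _subscore_frame({c: np.ones(3) for c in ALL_SUBSCORES})
        dims = dimension_scores(subs)
        np.testing.assert_allclose(dims.to_numpy(), 1.0)

    def test_all_zeros_gives_zeros(self):
        subs = _subscore_frame({c: np.zeros(3) for c in ALL_SUBSCORES})
        np.testing.assert_allclose(dimension_scores(subs).to_numpy(), 0.0)

    def test_plasma_dimension_is_mean_of_two(self):
        subs = _subscore_frame(
            {"plasma_dge": np.array([0.2]), "plasma_histo_r2": np.array([0.8])}
        )
        assert dimension_scores(subs)["plasma"].iloc[0] == pytest.approx(0.5)

    def test_sum_mode(self):
        subs = _subscore_frame({c: np.full(2, 0.5) for c in ALL_SUBSCORES})
        dims = dimension_scores(subs, aggregation="sum")
        assert dims["liver"].iloc[0] == pytest.approx(2.0)  # 4 subscores x 0.5

    def test_incomplete_table_rejected(self):
        subs = _subscore_frame({"plasma_dge": np.zeros(2)}).drop(columns=["plasma_dge"])
        with pytest.raises(ValueError, match="missing"):
            dimension_scores(subs)


class TestTotalScoreAndRank:
    def _dims(self, arr):
        return pd.DataFrame(
            np.asarray(arr, float),
            columns=list(DIMENSIONS),
            index=[f"g{i}" for i in range(len(arr))],
        )

    def test_perfect_candidate_scores_one_under_default(self):
        default = next(s for s in load_weight_settings() if s.name == "default")
        res = total_score_and_rank(self._dims([[1, 1, 1, 1]]), default)
        assert res["total"].iloc[0] == pytest.approx(1.0)

    def test_unit_weight_projects_single_dimension(self):
        rng = np.random.default_rng(1)
        dims = self._dims(rng.random((30, 4)))
        prior_only = WeightSetting("p", 0.0, 0.0, 1.0, 0.0)
        res = total_score_and_rank(dims, prior_only)
        by_dim = dims.sort_values("prior", ascending=False)
        assert list(res.index) == list(by_dim.index)
        np.testing.assert_allclose(res["total"], dims.loc[res.index, "prior"])

    def test_brute_force_dot_product_and_argsort(self):
        rng = np.random.default_rng(2)
        dims = self._dims(rng.random((50, 4)))
        w = WeightSetting("w", 0.1, 0.4, 0.3, 0.2)
        res = total_score_and_rank(dims, w)
        ref_totals = dims.to_numpy() @ np.array([0.1, 0.4, 0.3, 0.2])
        np.testing.assert_allclose(
            res["total"].sort_index(), pd.Series(ref_totals, index=dims.index).sort_index()
        )
        ref_order = np.argsort(-ref_totals, kind="stable")
        assert list(res.index) == [dims.index[i] for i in ref_order]
        assert sorted(res["rank"]) == list(range(1, 51))

    def test_ties_broken_by_candidate_id(self):
        dims = self._dims([[0.5, 0.5, 0.5, 0.5]] * 3)
        res = total_score_and_rank(dims, WeightSetting("w", 0.25, 0.25, 0.25, 0.25))
        assert list(res.index) == ["g0", "g1", "g2"]

    def test_contributions_sum_to_total(self):
        rng = np.random.default_rng(3)
        dims = self._dims(rng.random((10, 4)))
        res = total_score_and_rank(dims, load_weight_settings()[0])
        contrib = res[[f"contrib_{d}" for d in DIMENSIONS]].sum(axis=1)
        np.testing.assert_allclose(contrib, res["total"])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 11), st.floats(0.01, 0.5))
    def test_raising_a_subscore_never_lowers_total(self, sub_idx, bump):
        rng = np.random.default_rng(4)
        subs = _subscore_frame(
            {c: rng.random(8) for c in ALL_SUBSCORES}
        )
        col = ALL_SUBSCORES[sub_idx]
        bumped = subs.copy()
        bumped.loc["g3", col] = min(1.0, bumped.loc["g3", col] + bump)
        for setting in load_weight_settings():
            t0 = total_score_and_rank(dimension_scores(subs), setting)["total"]["g3"]
            t1 = total_score_and_rank(dimension_scores(bumped), setting)["total"]["g3"]
            assert t1 >= t0 - 1e-12


class TestSensitivity:
    def test_best_rank_is_min_across_settings(self):
        rng = np.random.default_rng(5)
        dims = pd.DataFrame(
            rng.random((20, 4)), columns=list(DIMENSIONS),
            index=[f"g{i}" for i in range(20)],
        )
        sens = sensitivity_analysis(dims, load_weight_settings())
        np.testing.assert_array_equal(
            sens["best_rank"].to_numpy(), sens["ranks"].min(axis=1).to_numpy()
        )
        assert set(sens["order"]) == set(dims.index)

    def test_consistent_winner_has_best_rank_one(self):
        dims = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [0.1, 0.2, 0.1, 0.3], [0.0, 0.0, 0.0, 0.0]],
            columns=list(DIMENSIONS), index=["winner", "mid", "low"],
        )
        sens = sensitivity_analysis(dims, load_weight_settings())
        assert sens["best_rank"]["winner"] == 1
        assert (sens["ranks"].loc["winner"] == 1).all()

    def test_duplicate_setting_names_rejected(self):
        dims = pd.DataFrame(
            [[0.5, 0.5, 0.5, 0.5]], columns=list(DIMENSIONS), index=["g0"]
        )
        w = WeightSetting("x", 0.25, 0.25, 0.25, 0.25)
        with pytest.raises(ValueError):
            sensitivity_analysis(dims, [w, w])
        with pytest.raises(ValueError):
            sensitivity_analysis(dims, [w])


class TestAssembleSubscores:
    def _inputs(self):
        genes = [f"g{i}" for i in range(6)]

        def de_tbl(feats, lfc=2.0, padj=0.001):
            return pd.DataFrame(
                {"feature_id": feats, "log2fc": lfc, "padj": padj}
            )

        de = {
            # g5 absent from plasma; all present in liver
            "plasma_protein": de_tbl(genes[:5]),
            "liver_protein": de_tbl(genes),
            "liver_rna": de_tbl(genes),
        }
        corr = {
            k: pd.DataFrame({"feature_id": genes, "r2": 0.5})
            for k in ("plasma_protein", "liver_protein", "liver_rna")
        }
        prior = pd.DataFrame(
            {
                "gene_id": genes[:4],  # g4, g5 have no prior evidence
                "fibrosis_association": 0.7,
                "publication_count": [0, 5, 10, 20],
                "expected_count": 1.0,
                "patent_flag": [0, 1, 0, 1],
                "database_flag": 0,
            }
        )
        id_map = pd.DataFrame(
            {
                "rat_protein_id": [f"p{i}" for i in range(6)],
                "rat_gene_id": genes,
                # g0 has no human ortholog
                "human_gene_id": [""] + [f"h{i}" for i in range(1, 6)],
                "human_protein_id": [""] + [f"hp{i}" for i in range(1, 6)],
                "secreted": [1, 1, 0, 0, 1, 0],
            }
        )
        return de, corr, prior, id_map

    def test_candidate_filter_ortholog_and_dual_detection(self):
        de, corr, prior, id_map = self._inputs()
        subs = assemble_subscores(de, corr, prior, id_map)
        # g0: no ortholog; g5: not detected in plasma
        assert list(subs.index) == ["g1", "g2", "g3", "g4"]

    def test_all_twelve_subscores_in_unit_interval(self):
        de, corr, prior, id_map = self._inputs()
        subs = assemble_subscores(de, corr, prior, id_map)
        assert list(subs.columns) == list(ALL_SUBSCORES)
        assert ((subs >= 0) & (subs <= 1)).all().all()

    def test_missing_prior_evidence_is_zero(self):
        de, corr, prior, id_map = self._inputs()
        subs = assemble_subscores(de, corr, prior, id_map)
        assert subs.loc["g4", "fibrosis_association"] == 0.0
        assert subs.loc["g4", "patent_flag"] == 0.0
        assert subs.loc["g4", "lit_pubcount"] == 0.0  # lowest count => rank 0

    def test_secreted_flag_passthrough(self):
        de, corr, prior, id_map = self._inputs()
        subs = assemble_subscores(de, corr, prior, id_map)
        assert subs.loc["g1", "secreted_flag"] == 1.0
        assert subs.loc["g2", "secreted_flag"] == 0.0

    def test_dimension_map_matches_table(self):
        flat = [s for subs in DIMENSION_SUBSCORES.values() for s in subs]
        assert len(flat) == 12
        assert len(DIMENSION_SUBSCORES["plasma"]) == 2
        assert len(DIMENSION_SUBSCORES["liver"]) == 4
        assert len(DIMENSION_SUBSCORES["prior"]) == 5
        assert len(DIMENSION_SUBSCORES["secreted"]) == 1

    def test_empty_candidates_rejected(self):
        de, corr, prior, id_map = self._inputs()
        id_map["human_gene_id"] = ""
        with pytest.raises(ValueError, match="empty"):
            assemble_subscores(de, corr, prior, id_map)
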