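"""Normalization, t-score ranking, heatmaps, Venn logic, filters, enrichment."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exosig import diffsig, synthio
from exosig.errors import ConfigError, DataError


def protein_table(data, samples):
    return pd.DataFrame(data, columns=samples,
                        index=pd.Index([f"P{i}" for i in range(len(data))],
                                       name="protein_id"))


def two_cohort_sheet(n1=3, n2=3, labels=("c1", "c2")):
    ids = [f"{labels[0]}_s{i}" for i in range(n1)] + [
        f"{labels[1]}_s{i}" for i in range(n2)
    ]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "group": [labels[0]] * n1 + [labels[1]] * n2,
            "cohort": [labels[0]] * n1 + [labels[1]] * n2,
            "replicate": list(range(1, n1 + 1)) + list(range(1, n2 + 1)),
            "dfi_days": pd.NA,
        }
    ), ids


class TestNormalizeColumns:
    def test_column_sums_to_one(self):
        tbl = protein_table([[1.0, 4.0], [1.0, 4.0], [2.0, 8.0]], ["s1", "s2"])
        out = diffsig.normalize_columns(tbl)
        assert out["s1"].tolist() == pytest.approx([0.25, 0.25, 0.5])
        assert out.sum(axis=0).to_numpy() == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_idempotent(self):
        tbl = protein_table([[0.25, 0.1], [0.75, 0.9]], ["s1", "s2"])
        out = diffsig.normalize_columns(tbl)
        pd.testing.assert_frame_equal(out, tbl)

    def test_zero_column_names_sample(self):
        tbl = protein_table([[1.0, 0.0], [1.0, 0.0]], ["good", "empty"])
        with pytest.raises(DataError, match="empty"):
            diffsig.normalize_columns(tbl)


class TestFeatureTScores:
    def test_pooled_t_hand_example(self):
        sheet, ids = two_cohort_sheet(3, 3)
        tbl = protein_table([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], ids)
        sc = diffsig.feature_t_scores(tbl, sheet, "c1", "c2", normalize=False)
        assert sc.loc[0, "t_score"] == pytest.approx(-3.674, abs=1e-3)
        assert sc.loc[0, "p_value"] == pytest.approx(0.0214, abs=1e-3)
        assert sc.loc[0, "direction"] == "negative"

    def test_identical_cohorts_null(self):
        sheet, ids = two_cohort_sheet(3, 3)
        tbl = protein_table([[2.0] * 6], ids)
        sc = diffsig.feature_t_scores(tbl, sheet, "c1", "c2", normalize=False)
        assert sc.loc[0, "t_score"] == 0.0
        assert sc.loc[0, "p_value"] == 1.0

    def test_zero_variance_unequal_means_gives_inf_sentinel(self):
        sheet, ids = two_cohort_sheet(2, 2)
        tbl = protein_table([[1.0, 1.0, 2.0, 2.0], [1, 2, 3, 4]], ids)
        sc = diffsig.feature_t_scores(tbl, sheet, "c1", "c2", normalize=False)
        row = sc.set_index("protein_id").loc["P0"]
        assert np.isneginf(row["t_score"]) and row["p_value"] == 0.0

    def test_label_swap_negates_t_and_reverses_order(self):
        cfg = synthio.serum_config(seed=4, n_proteins=60)
        tbl, sheet, _ = synthio.simulate_serum_cohorts(cfg)
        fwd = diffsig.feature_t_scores(tbl, sheet, "good", "poor")
        rev = diffsig.feature_t_scores(tbl, sheet, "poor", "good")
        f = fwd.set_index("protein_id")
        r = rev.set_index("protein_id")
        assert np.allclose(f["t_score"], -r.loc[f.index, "t_score"])
        assert np.allclose(f["p_value"], r.loc[f.index, "p_value"])
        assert fwd["protein_id"].tolist() == rev["protein_id"].tolist()[::-1]

    def test_welch_flag_differs_under_heteroscedasticity(self):
        sheet, ids = two_cohort_sheet(3, 3)
        tbl = protein_table([[1.0, 2.0, 3.0, 10.0, 30.0, 50.0]], ids)
        pooled = diffsig.feature_t_scores(tbl, sheet, "c1", "c2", normalize=False)
        welch = diffsig.feature_t_scores(
            tbl, sheet, "c1", "c2", equal_var=False, normalize=False
        )
        ref = stats.ttest_ind([1, 2, 3], [10, 30, 50], equal_var=False)
        assert welch.loc[0, "t_score"] == pytest.approx(ref.statistic)
        assert welch.loc[0, "p_value"] == pytest.approx(ref.pvalue)
        assert welch.loc[0, "p_value"] != pytest.approx(pooled.loc[0, "p_value"])


class TestHeatmap:
    def test_reference_relative_log2(self):
        sheet, ids = two_cohort_sheet(2, 2)
        # row P0: sample c2_s0 equals ref mean -> 0; c2_s1 is twice it -> ~1
        tbl = protein_table(
            [[0.3, 0.5, 0.4, 0.8], [0.7, 0.5, 0.6, 0.2]], ids
        )
        sc = diffsig.feature_t_scores(tbl, sheet, "c1", "c2", normalize=False)
        hm = diffsig.heatmap_matrix(tbl, sheet, "c1", sc, normalize=False)
        assert hm.values.loc["P0", ids[2]] == pytest.approx(0.0, abs=1e-6)
        assert hm.values.loc["P0", ids[3]] == pytest.approx(1.0, abs=1e-6)
        assert hm.row_order == sc["protein_id"].tolist()

    def test_reference_cohort_mean_profile_is_zero(self):
        cfg = synthio.serum_config(seed=6, n_proteins=40)
        tbl, sheet, _ = synthio.simulate_serum_cohorts(cfg)
        sc = diffsig.feature_t_scores(tbl, sheet, "good", "poor")
        hm = diffsig.heatmap_matrix(tbl, sheet, "good", sc)
        # mean of 2^value over reference columns is 1 -> log2-mean profile ~ 0
        ref_linear = np.exp2(hm.values[hm.reference_columns])
        assert np.allclose(ref_linear.mean(axis=1), 1.0, atol=1e-6)


class TestDetectionSets:
    def test_three_group_regions(self):
        regions = diffsig.detection_sets(
            {"A": {1, 2}, "B": {2, 3}, "C": {2}}
        )
        assert regions["A"]["ids"] == [1]
        assert regions["B"]["ids"] == [3]
        assert regions["C"]["count"] == 0
        assert regions["A&B&C"]["ids"] == [2]
        assert regions["A&B"]["count"] == 0

    @pytest.mark.parametrize(
        "presence",
        [
            {"A": {1, 2, 3}, "B": {4, 5}, "C": {6}},           # disjoint
            {"A": {1, 2}, "B": {1, 2}, "C": {1, 2}},           # identical
            {"A": set(), "B": {1}, "C": {1, 2}},               # one empty
        ],
    )
    def test_regions_partition_the_union(self, presence):
        regions = diffsig.detection_sets(presence)
        union = set().union(*presence.values())
        total = sum(r["count"] for r in regions.values())
        assert total == len(union)
        all_ids = [i for r in regions.values() for i in r["ids"]]
        assert len(all_ids) == len(set(all_ids))

    def test_more_than_three_groups_unsupported(self):
        with pytest.raises(ConfigError):
            diffsig.detection_sets({"A": set(), "B": set(), "C": set(), "D": set()})

    def test_presence_from_peptide_table(self, tiny_peptides):
        tbl, sheet = tiny_peptides
        tbl = tbl.copy()
        tbl.loc["PA_pep1", ["B_r1", "B_r2"]] = np.nan  # PA now A-only
        pres = diffsig.presence_from_peptide_table(tbl, sheet)
        assert "PA" in pres["A"] and "PA" not in pres["B"]
        assert pres["A"] >= {"PB", "PC"} and pres["B"] >= {"PB", "PC"}


class TestOrthologFilter:
    def test_strictly_greater_than_99(self):
        rows = pd.DataFrame(
            {"protein_id": ["P1", "P2", "P3", "P4"],
             "percent_similarity": [99.5, 98.0, 100.0, 99.0]}
        )
        assert diffsig.ortholog_similarity_filter(rows) == ["P1", "P3"]

    def test_empty_and_out_of_range(self):
        assert diffsig.ortholog_similarity_filter(pd.DataFrame()) == []
        bad = pd.DataFrame({"protein_id": ["P1"], "percent_similarity": [101.0]})
        with pytest.raises(DataError):
            diffsig.ortholog_similarity_filter(bad)


class TestEnrichment:
    def _collection(self):
        bg = [f"g{i}" for i in range(20)]
        return bg, diffsig.GeneSetCollection.from_dict(
            {"S": bg[:5]}, background=bg
        )

    def test_hand_enumerated_table(self):
        bg, coll = self._collection()
        query = bg[2:8]  # overlap with S = {g2, g3, g4} -> a=3, b=3, c=2, d=12
        out = diffsig.enrichment_odds_ratios(query, coll).iloc[0]
        assert out["odds_ratio"] == pytest.approx(6.0)
        assert out["p_value"] == pytest.approx(0.13131, abs=1e-4)

    def test_depletion_and_extreme_cases(self):
        bg, coll = self._collection()
        disjoint = diffsig.enrichment_odds_ratios(bg[5:11], coll).iloc[0]
        assert disjoint["odds_ratio"] < 1.0 and disjoint["p_value"] >= 0.5
        exact = diffsig.enrichment_odds_ratios(bg[:5], coll).iloc[0]
        # query == set: minimal possible tail p for these margins, 1/C(20,5)
        assert exact["p_value"] == pytest.approx(
            float(stats.hypergeom.pmf(5, 20, 5, 5))
        )

    def test_super_uniform_under_random_queries(self, rng):
        bg = [f"g{i}" for i in range(200)]
        coll = diffsig.GeneSetCollection.from_dict(
            {"S": bg[:30]}, background=bg
        )
        pvals = []
        for _ in range(2000):
            q = rng.choice(200, size=25, replace=False)
            out = diffsig.enrichment_odds_ratios([bg[i] for i in q], coll)
            pvals.append(out.loc[0, "p_value"])
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.2):
            se = np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert (pvals <= alpha).mean() <= alpha + 4 * se

    def test_argument_errors(self):
        bg, coll = self._collection()
        with pytest.raises(ConfigError):
            diffsig.enrichment_odds_ratios([], coll)
        with pytest.raises(ConfigError):
            diffsig.enrichment_odds_ratios(["not_in_bg"], coll)

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("alpha\tdesc\tg1\tg2\tg3\nbeta\t-\tg2\tg4\n")
        coll = diffsig.read_gmt(path, background=[f"g{i}" for i in range(1, 6)])
        assert coll.sets["alpha"] == frozenset({"g1", "g2", "g3"})
        assert coll.sets["beta"] == frozenset({"g2", "g4"})
        with pytest.raises(DataError):
            (tmp_path / "bad.gmt").write_text("only_one_field\n")
            diffsig.read_gmt(tmp_path / "bad.gmt")
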