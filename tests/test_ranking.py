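import numpy as np
import pandas as pd
import pytest

from sigtarget import ranking
from sigtarget.errors import SchemaError, TrainingError
from sigtarget.ranking import (
    RankedTargets,
    loocv,
    make_training_pairs,
    predict_ranking,
    rank_by_feature,
    rank_in_active_cell,
    read_rankings,
    train_logistic,
    train_rf_on_the_fly,
    train_rf_two_level,
    write_rankings,
)


def make_table(rows):
    """rows: (drug, gene, cell, f_cor, f_PC, f_CS, f_DE_mean, f_DE_max, f_loc)"""
    return pd.DataFrame(
        rows,
        columns=["drug", "gene", "cell", "f_cor", "f_PC", "f_CS", "f_DE_mean",
                 "f_DE_max", "f_loc"],
    )


class TestRankByFeature:
    def test_lowest_rank_across_cells(self):
        # gene with per-cell ranks {c1: 2, c2: 1} beats gene ranked {1, 2}?
        # no — both aggregate to 1; construct the documented case instead
        rows = []
        # g_best: rank 5 in c1, rank 300-ish (worst) in c2
        for i in range(6):
            rows.append(("d", f"g{i}", "c1", 0.9 - 0.1 * i, 0, 0, 0, 0, 0))
            rows.append(("d", f"g{i}", "c2", 0.1 * i, 0, 0, 0, 0, 0))
        table = make_table(rows)
        rt = rank_by_feature(table, "f_cor")
        # every gene's aggregate is min(rank_c1, rank_c2)
        # g0: min(1, 6)=1; g5: min(6, 1)=1 -> tie broken lexicographically
        assert rt.genes[0] == "g0"
        assert rt.genes[1] == "g5"

    def test_min_over_cells_value(self):
        rows = [
            ("d", "a", "c1", 0.2, 0, 0, 0, 0, 0),
            ("d", "b", "c1", 0.9, 0, 0, 0, 0, 0),
            ("d", "a", "c2", 0.9, 0, 0, 0, 0, 0),
            ("d", "b", "c2", 0.2, 0, 0, 0, 0, 0),
        ]
        rt = rank_by_feature(make_table(rows), "f_cor")
        # both genes reach rank 1 in one cell
        assert list(rt.scores) == [-1.0, -1.0]
        assert rt.genes == ["a", "b"]  # lexicographic tie-break

    def test_single_cell_matches_per_cell_ranking(self):
        rows = [
            ("d", "a", "c1", 0.1, 0, 0, 0, 0, 0),
            ("d", "b", "c1", 0.9, 0, 0, 0, 0, 0),
            ("d", "c", "c1", 0.5, 0, 0, 0, 0, 0),
        ]
        rt = rank_by_feature(make_table(rows), "f_cor")
        assert rt.genes == ["b", "c", "a"]

    def test_unknown_feature(self):
        with pytest.raises(KeyError):
            rank_by_feature(make_table([("d", "a", "c1", 0, 0, 0, 0, 0, 0)]),
                            "f_zzz")

    def test_complete_permutation(self, small_features):
        drug = small_features["drug"].iloc[0]
        sub = small_features[small_features["drug"] == drug].reset_index(drop=True)
        rt = rank_by_feature(sub, "f_PC")
        assert sorted(rt.genes) == sorted(sub["gene"].unique())
        assert list(rt.ranks) == list(range(1, len(rt.genes) + 1))


class TestRankInActiveCell:
    def test_argmin_cell_selected(self):
        rows = [
            ("d", "a", "c1", 0.9, 0, 0.9, 0, 0, 0),
            ("d", "b", "c1", 0.1, 0, 0.9, 0, 0, 0),
            ("d", "a", "c2", 0.1, 0, 0.2, 0, 0, 0),
            ("d", "b", "c2", 0.9, 0, 0.2, 0, 0, 0),
        ]
        rt = rank_in_active_cell(make_table(rows))
        assert rt.genes == ["b", "a"]  # ranking from the 0.2-correlation cell

    def test_equal_cs_prefers_first_cell(self):
        rows = [
            ("d", "a", "c1", 0.9, 0, 0.5, 0, 0, 0),
            ("d", "b", "c1", 0.1, 0, 0.5, 0, 0, 0),
            ("d", "a", "c2", 0.1, 0, 0.5, 0, 0, 0),
            ("d", "b", "c2", 0.9, 0, 0.5, 0, 0, 0),
        ]
        rt = rank_in_active_cell(make_table(rows))
        assert rt.genes == ["a", "b"]

    def test_single_cell_equals_dir(self):
        rows = [
            ("d", "a", "c1", 0.3, 0, 0.5, 0, 0, 0),
            ("d", "b", "c1", 0.8, 0, 0.5, 0, 0, 0),
        ]
        assert rank_in_active_cell(make_table(rows)).genes == rank_by_feature(
            make_table(rows), "f_cor"
        ).genes


class TestMakeTrainingPairs:
    def _table(self, n_genes=120):
        rows = [("d1", f"g{i:03d}", "c1", 0.0, 0, 0, 0, 0, 0)
                for i in range(n_genes)]
        return make_table(rows)

    def test_ratio_arithmetic(self):
        table = self._table()
        targets = {"d1": {"g000", "g001"}}
        pairs = make_training_pairs(table, targets, negative_ratio=50, seed=0)
        assert (pairs["label"] == 1).sum() == 2
        assert (pairs["label"] == 0).sum() == 100

    def test_ratio_all(self):
        table = self._table()
        pairs = make_training_pairs(table, {"d1": {"g000"}}, negative_ratio="all")
        assert (pairs["label"] == 0).sum() == 119

    def test_seeded_determinism(self):
        table = self._table()
        targets = {"d1": {"g000"}}
        a = make_training_pairs(table, targets, negative_ratio=10, seed=5)
        b = make_training_pairs(table, targets, negative_ratio=10, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = make_training_pairs(table, targets, negative_ratio=10, seed=6)
        assert not a.equals(c)

    def test_drug_without_inframe_target_excluded(self):
        table = self._table()
        pairs = make_training_pairs(table, {"d1": {"not_a_gene"}})
        assert pairs.empty


def _separable_table(n_drugs=6, n_genes=30, n_cells=2):
    """Positives have f_cor ~0.9, negatives ~-0.9; trivially separable."""
    rng = np.random.default_rng(0)
    rows = []
    targets = {}
    for d in range(n_drugs):
        drug = f"d{d}"
        targets[drug] = {f"g00"}
        for g in range(n_genes):
            gene = f"g{g:02d}"
            for c in range(n_cells):
                base = 0.9 if gene in targets[drug] else -0.9
                rows.append(
                    (drug, gene, f"c{c}", base + rng.normal(0, 0.01),
                     rng.random(), 0.1 * c, rng.random(), 1 + rng.random(), 0)
                )
    return make_table(rows), targets


def _logistic_toy_table(n_drugs=6, n_genes=20, n_cells=2):
    """Only f_cor is informative; every other feature is constant."""
    rng = np.random.default_rng(0)
    rows = []
    targets = {}
    for d in range(n_drugs):
        drug = f"d{d}"
        targets[drug] = {"g00"}
        for g in range(n_genes):
            gene = f"g{g:02d}"
            base = 0.9 if gene == "g00" else -0.9
            for c in range(n_cells):
                rows.append((drug, gene, f"c{c}", base + rng.normal(0, 0.005),
                             1.0, 0.5, 1.0, 2.0, 0))
    return make_table(rows), targets


class TestLogistic:
    def test_separates_toy_set(self):
        table, targets = _logistic_toy_table()
        pairs = make_training_pairs(table, targets, negative_ratio="all", seed=0)
        model = train_logistic(table, pairs, seed=0)
        for drug in targets:
            rt = predict_ranking(model,
                                 table[table["drug"] == drug]
                                 .reset_index(drop=True))
            # all positives scored above all negatives
            assert rt.genes[0] == "g00"
            assert rt.scores[0] > rt.scores[1]

    def test_single_class_errors(self):
        table, targets = _separable_table()
        pairs = make_training_pairs(table, targets, negative_ratio="all", seed=0)
        with pytest.raises(TrainingError):
            train_logistic(table, pairs[pairs["label"] == 1], seed=0)

    def test_duplicated_rows_same_ordering(self):
        table, targets = _logistic_toy_table()
        pairs = make_training_pairs(table, targets, negative_ratio="all", seed=0)
        m1 = train_logistic(table, pairs, seed=0)
        m2 = train_logistic(table, pd.concat([pairs, pairs], ignore_index=True),
                            seed=0)
        q = table[table["drug"] == "d1"].reset_index(drop=True)
        assert predict_ranking(m1, q).genes == predict_ranking(m2, q).genes


class TestTwoLevel:
    def test_heterogeneous_cell_counts_pool(self):
        table, targets = _separable_table(n_drugs=4, n_cells=2)
        extra, extra_targets = _separable_table(n_drugs=2, n_cells=3)
        extra["drug"] = extra["drug"].map({"d0": "e0", "d1": "e1"})
        merged = pd.concat([table, extra], ignore_index=True)
        targets.update({"e0": {"g00"}, "e1": {"g00"}})
        pairs = make_training_pairs(merged, targets, negative_ratio=10, seed=0)
        model = train_rf_two_level(merged, pairs, seed=0, n_trees=30)
        rt = predict_ranking(model, merged[merged["drug"] == "e0"]
                             .reset_index(drop=True))
        assert rt.genes[0] == "g00"

    def test_seeded_determinism(self):
        table, targets = _separable_table()
        pairs = make_training_pairs(table, targets, negative_ratio=10, seed=0)
        q = table[table["drug"] == "d0"].reset_index(drop=True)
        a = predict_ranking(train_rf_two_level(table, pairs, seed=3, n_trees=30), q)
        b = predict_ranking(train_rf_two_level(table, pairs, seed=3, n_trees=30), q)
        assert a.genes == b.genes
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_empty_examples_error(self):
        table, _ = _separable_table()
        with pytest.raises(TrainingError):
            train_rf_two_level(table, pd.DataFrame(columns=["drug", "gene",
                                                            "label"]), seed=0)


class TestOnTheFly:
    def test_restricts_to_query_cells(self):
        # training drugs profiled in {c0, c1, c2}; query only {c0, c1}
        table, targets = _separable_table(n_drugs=5, n_cells=3)
        query = table[(table["drug"] == "d0") & (table["cell"] != "c2")]
        rest = table[table["drug"] != "d0"]
        merged = pd.concat([query, rest], ignore_index=True)
        pairs = make_training_pairs(merged, targets, negative_ratio=10, seed=0,
                                    drugs=[f"d{i}" for i in range(1, 5)])
        model = train_rf_on_the_fly("d0", merged, pairs, seed=0, n_trees=30)
        assert model.cells == ["c0", "c1"]
        rt = predict_ranking(model, merged[merged["drug"] == "d0"]
                             .reset_index(drop=True))
        assert rt.genes[0] == "g00"

    def test_no_compatible_training_drugs(self):
        table, targets = _separable_table(n_drugs=3, n_cells=1)
        query = table[table["drug"] == "d0"].copy()
        query["cell"] = "cz"  # a cell no training drug has
        merged = pd.concat([query, table[table["drug"] != "d0"]],
                           ignore_index=True)
        pairs = make_training_pairs(merged, targets, negative_ratio=10, seed=0,
                                    drugs=["d1", "d2"])
        with pytest.raises(TrainingError, match="two-level"):
            train_rf_on_the_fly("d0", merged, pairs, seed=0, n_trees=10)

    def test_cell_order_canonical(self):
        table, targets = _separable_table(n_drugs=4, n_cells=2)
        pairs = make_training_pairs(table, targets, negative_ratio=10, seed=0,
                                    drugs=["d1", "d2", "d3"])
        shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        m1 = train_rf_on_the_fly("d0", table, pairs, seed=0, n_trees=30)
        m2 = train_rf_on_the_fly("d0", shuffled, pairs, seed=0, n_trees=30)
        q = table[table["drug"] == "d0"].reset_index(drop=True)
        assert predict_ranking(m1, q).genes == predict_ranking(m2, q).genes


class TestPredictRanking:
    def test_tie_cascade_uses_best_f_cor(self):
        rt = ranking._order_by_score(
            "d", ["a", "b", "c"], np.array([0.9, 0.9, 0.1]),
            np.array([0.2, 0.8, 0.0]),
        )
        assert rt.genes == ["b", "a", "c"]

    def test_missing_feature_column_errors(self):
        table, targets = _separable_table()
        pairs = make_training_pairs(table, targets, negative_ratio=10, seed=0)
        model = train_rf_two_level(table, pairs, seed=0, n_trees=10)
        broken = table[table["drug"] == "d0"].drop(columns=["f_PC"])
        with pytest.raises(SchemaError, match="f_PC"):
            predict_ranking(model, broken.reset_index(drop=True))

    def test_incomplete_cell_coverage_errors(self):
        table, targets = _separable_table(n_cells=2)
        pairs = make_training_pairs(table, targets, negative_ratio=10, seed=0)
        model = train_rf_two_level(table, pairs, seed=0, n_trees=10)
        q = table[table["drug"] == "d0"]
        q = q.drop(q[(q["gene"] == "g01") & (q["cell"] == "c1")].index)
        with pytest.raises(SchemaError):
            predict_ranking(model, q.reset_index(drop=True))


class TestLoocv:
    def test_shapes_and_no_leakage(self, small_features, small_bundle,
                                   monkeypatch):
        targets = small_bundle.targets
        seen_training_drugs = []
        orig = ranking.train_rf_two_level

        def spy(table, pairs, **kw):
            seen_training_drugs.append(set(pairs["drug"]))
            return orig(table, pairs, **kw)

        monkeypatch.setattr(ranking, "train_rf_two_level", spy)
        rankings, failures = loocv(
            small_features, targets, "rf_two_level", seed=0, negative_ratio=10,
            n_trees=20,
        )
        assert not failures
        drugs = sorted(small_features["drug"].unique())
        assert sorted(rankings) == drugs
        for i, drug in enumerate(drugs):
            assert drug not in seen_training_drugs[i]  # leakage check
            pool = small_features[small_features["drug"] == drug]["gene"].nunique()
            assert len(rankings[drug].genes) == pool

    def test_too_few_drugs(self, small_features, small_bundle):
        two = small_features[small_features["drug"].isin(
            sorted(small_features["drug"].unique())[:2])]
        with pytest.raises(TrainingError):
            loocv(two, small_bundle.targets, "rf_two_level")


class TestSerialization:
    def test_round_trip_idempotent(self, tmp_path, small_features):
        rankings = {
            d: rank_by_feature(sub.reset_index(drop=True), "f_cor")
            for d, sub in small_features.groupby("drug")
        }
        path = tmp_path / "ranks.tsv"
        write_rankings(rankings, path)
        back = read_rankings(path)
        for d in rankings:
            assert back[d].genes == rankings[d].genes
        path2 = tmp_path / "ranks2.tsv"
        write_rankings(back, path2)
        assert path.read_text() == path2.read_text()

    def test_scores_nonincreasing_enforced(self):
        with pytest.raises(ValueError):
            RankedTargets("d", ["a", "b"], np.array([0.1, 0.9]))
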