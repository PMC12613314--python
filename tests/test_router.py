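"""Random-forest routing: training, vote semantics, fallback, importance."""

import numpy as np
import pandas as pd
import pytest

from edcorr.features import FEATURE_COLUMNS
from edcorr.library import train_library
from edcorr.linear import baseline_model, predict
from edcorr.metrics import evaluate
from edcorr.router import (
    RouterModel,
    permutation_importance,
    route_predict,
    route_predict_table,
    train_router,
    vote_fraction,
)
from edcorr.simulate import SynthConfig, generate_dataset

from conftest import random_feature_table


def _two_class_table(rng, n=60, gap=100.0):
    """Two perfectly separated classes along every feature."""
    rows = []
    for cls, centre in (("SMALL", gap), ("LARGE", -gap)):
        for i in range(n):
            feats = rng.normal(centre, 1.0, size=7)
            row = {"reaction_id": f"{cls}{i}", **dict(zip(FEATURE_COLUMNS, feats)),
                   "superset": cls, "ref_energy": float(np.sum(feats))}
            rows.append(row)
    return pd.DataFrame(rows)


class TestTrainRouter:
    def test_separable_classes_reach_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        table = _two_class_table(rng)
        router = train_router(table, seed=0, tree_grid=(50,), depth_grid=(None,))
        assert router.test_accuracy == 1.0

    def test_shuffled_labels_give_chance_accuracy(self):
        table, _ = generate_dataset(SynthConfig(n_per_class=80, seed=2))
        rng = np.random.default_rng(3)
        table = table.copy()
        table["superset"] = rng.permutation(table["superset"].to_numpy())
        router = train_router(table, seed=0, tree_grid=(100,), depth_grid=(8,))
        n_test = len(router.test_index)
        # 5 balanced classes: accuracy ~ Binomial(n_test, 0.2) / n_test
        half_width = 1.96 * np.sqrt(0.2 * 0.8 / n_test)
        assert abs(router.test_accuracy - 0.2) < half_width + 0.05

    def test_single_class_rejected(self):
        rng = np.random.default_rng(1)
        table = _two_class_table(rng)
        table["superset"] = "SMALL"
        with pytest.raises(ValueError, match="two"):
            train_router(table)

    def test_deterministic_hyperparameter_selection(self, small_world):
        table, _ = small_world
        a = train_router(table, seed=5, tree_grid=(50, 100), depth_grid=(4, None))
        b = train_router(table, seed=5, tree_grid=(50, 100), depth_grid=(4, None))
        assert a.forest.n_estimators == b.forest.n_estimators
        assert a.forest.max_depth == b.forest.max_depth
        assert a.test_accuracy == b.test_accuracy

    def test_search_record_covers_grid(self, small_router):
        assert len(small_router.search_record) == 4  # 2 tree counts x 2 depths


class TestVoteFraction:
    def test_fraction_counts_trees(self, small_router, small_world):
        table, _ = small_world
        label, frac = vote_fraction(small_router, table.iloc[[0]])
        n_trees = len(small_router.forest.estimators_)
        assert 0.0 < frac <= 1.0
        assert (frac * n_trees) == pytest.approx(round(frac * n_trees))
        assert label in small_router.classes

    def test_unanimous_vote_is_one(self):
        rng = np.random.default_rng(4)
        table = _two_class_table(rng)
        router = train_router(table, seed=0, tree_grid=(50,), depth_grid=(None,))
        label, frac = vote_fraction(router, table.iloc[[0]])
        assert frac == 1.0
        assert label == "SMALL"

    def test_tie_breaks_alphabetically(self, small_router):
        # force a hand-built 50/50 situation through the counting logic
        counts = np.array([30, 30])
        classes = np.array(["LARGE", "BARRIER"])
        order = np.argsort(classes)
        winner = classes[order][np.argmax(counts[order])]
        assert winner == "BARRIER"


@pytest.fixture(scope="module")
def routed_world(small_world, small_library, small_router):
    table, _ = small_world
    library, _ = small_library
    return table, library, small_router


@pytest.fixture(scope="module")
def constructed_importance():
    """Labels defined purely by the sign of d_ex; d_vnn is pure noise."""
    rng = np.random.default_rng(6)
    n = 240
    data = {c: rng.normal(0, 5, n) for c in FEATURE_COLUMNS}
    table = pd.DataFrame({"reaction_id": [f"r{i}" for i in range(n)], **data})
    table["superset"] = np.where(table["d_ex"] > 0, "SMALL", "LARGE")
    table["ref_energy"] = 1.0
    router = train_router(table, seed=0, tree_grid=(100,), depth_grid=(None,))
    report = permutation_importance(router, table, n_rounds=30, seed=0)
    return table, router, report


class TestRoutePredict:
    def test_threshold_boundary_semantics(self, routed_world):
        table, library, router = routed_world
        row = table.iloc[[0]]
        label, frac = vote_fraction(router, row)
        router_hi = RouterModel(forest=router.forest, classes=router.classes,
                                vote_threshold=min(frac + 1e-9, 1.0))
        router_at = RouterModel(forest=router.forest, classes=router.classes,
                                vote_threshold=frac)
        _, used_at, _ = route_predict(router_at, library, row)
        assert used_at == label  # exactly at threshold routes specialised
        if frac < 1.0:
            _, used_hi, _ = route_predict(router_hi, library, row)
            assert used_hi == "FULL"

    def test_missing_superset_model_falls_back(self, routed_world):
        table, library, router = routed_world
        import copy
        lib = copy.deepcopy(library)
        sub = table[table["superset"] == "INTER"]
        row = sub.iloc[[0]]
        label, frac = vote_fraction(router, row)
        if label in lib.superset_models:
            del lib.superset_models[label]
        _, used, _ = route_predict(router, lib, row)
        assert used == "FULL"

    def test_fallback_count_monotone_in_threshold(self, routed_world):
        table, library, router = routed_world
        counts = []
        for thr in (0.2, 0.5, 0.7, 0.9, 1.0):
            r = RouterModel(forest=router.forest, classes=router.classes,
                            vote_threshold=thr)
            routed = route_predict_table(r, library, table)
            counts.append(int((routed["chosen_model"] == "FULL").sum()))
        assert counts == sorted(counts)

    def test_table_and_row_paths_agree(self, routed_world):
        table, library, router = routed_world
        routed = route_predict_table(router, library, table.head(10))
        for i in range(10):
            e, label, frac = route_predict(router, library, table.iloc[[i]])
            assert e == pytest.approx(routed["prediction"].iloc[i], rel=1e-12)
            assert label == routed["chosen_model"].iloc[i]
            assert frac == pytest.approx(routed["vote_fraction"].iloc[i])

    def test_end_to_end_dominance(self, routed_world):
        table, library, router = routed_world
        refs = table["ref_energy"].to_numpy(float)
        mape_base = evaluate(predict(baseline_model(), table), refs).mape
        mape_full = evaluate(predict(library.full_model, table), refs).mape
        routed = route_predict_table(router, library, table)
        mape_rf = evaluate(routed["prediction"].to_numpy(), refs).mape
        assert mape_rf <= mape_full - 1e-6
        assert mape_full <= mape_base - 1e-6

    def test_out_of_distribution_rows_stay_finite(self, routed_world):
        table, library, router = routed_world
        far = table.head(50).copy()
        for c in FEATURE_COLUMNS:
            far[c] = far[c] * 10.0
        routed = route_predict_table(router, library, far)
        assert np.all(np.isfinite(routed["prediction"]))
        assert 0.0 <= (routed["chosen_model"] == "FULL").mean() <= 1.0


class TestPermutationImportance:
    def test_label_defining_feature_ranks_first(self, constructed_importance):
        _, _, report = constructed_importance
        for metric in ("accuracy", "f1", "precision", "recall"):
            assert report.ranking(metric, "test")[0] == "d_ex"

    def test_noise_feature_importance_near_zero(self, constructed_importance):
        _, _, report = constructed_importance
        frame = report.to_frame()
        row = frame[(frame["feature"] == "d_vnn") & (frame["metric"] == "accuracy")
                    & (frame["subset"] == "test")].iloc[0]
        assert abs(row["mean"]) <= 2 * max(row["sd"], 1e-9) + 1e-9

    def test_fixed_seed_reproducible(self, constructed_importance):
        table, router, report = constructed_importance
        again = permutation_importance(router, table, n_rounds=30, seed=0)
        pd.testing.assert_frame_equal(report.to_frame(), again.to_frame())

    def test_invalid_rounds_rejected(self, constructed_importance):
        table, router, _ = constructed_importance
        with pytest.raises(ValueError, match="n_rounds"):
            permutation_importance(router, table, n_rounds=0)

    def test_matches_sklearn_accuracy_importance(self, constructed_importance):
        # independent cross-check of the accuracy channel on the test split
        from sklearn.inspection import permutation_importance as sk_pi
        table, router, report = constructed_importance
        labelled = table.reset_index(drop=True)
        X = labelled[list(FEATURE_COLUMNS)].to_numpy(float)
        y = labelled["superset"].to_numpy()
        Xt, yt = X[router.test_index], y[router.test_index]
        sk = sk_pi(router.forest, Xt, yt, n_repeats=60, random_state=1,
                   scoring="accuracy")
        frame = report.to_frame()
        ours = frame[(frame["metric"] == "accuracy") & (frame["subset"] == "test")]
        ours = ours.set_index("feature")["mean"]
        for j, feat in enumerate(FEATURE_COLUMNS):
            band = 3 * max(sk.importances_std[j], 0.02)
            assert abs(ours[feat] - sk.importances_mean[j]) <= band


class TestRouterSerialization:
    def test_archive_round_trip(self, small_router, tmp_path):
        p = tmp_path / "router.joblib"
        small_router.save(p)
        back = RouterModel.load(p)
        assert back.vote_threshold == small_router.vote_threshold
        assert back.classes == small_router.classes
        assert back.test_accuracy == small_router.test_accuracy
        assert np.array_equal(back.train_index, small_router.train_index)

    def test_fixed_seed_training_byte_identical(self, small_world, tmp_path):
        table, _ = small_world
        p1, p2 = tmp_path / "r1.joblib", tmp_path / "r2.joblib"
        train_router(table, seed=8, tree_grid=(50,), depth_grid=(8,)).save(p1)
        train_router(table, seed=8, tree_grid=(50,), depth_grid=(8,)).save(p2)
        assert p1.read_bytes() == p2.read_bytes()
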