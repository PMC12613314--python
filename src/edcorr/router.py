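"""Random-forest routing of reactions to correction models.

A random forest is trained on the same seven unnormalised delta
descriptors the linear models use, to predict which reaction class a
reaction belongs to.  At prediction time the fraction of trees voting
for the winning class serves as a confidence score: if it reaches the
vote threshold (default 0.70) and the class has a model in the library,
the class-specific model is used; otherwise the prediction falls back
to the global FULL model.  Exactly the threshold value routes to the
specialised model (only votes strictly below it fall back).

Hyperparameters (tree count and maximum depth, including unlimited
growth to pure leaves under the Gini criterion) are chosen by grid
search on a stratified 80/20 split, maximising held-out accuracy with
ties going to the smaller forest.

Permutation feature importance is computed by shuffling one descriptor
column at a time and recording the drop in accuracy, macro-F1, macro-
precision and macro-recall, averaged over permutation rounds, on the
training and test subsets separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import train_test_split

from edcorr.features import FEATURE_COLUMNS
from edcorr.library import ModelLibrary
from edcorr.linear import SCHEMA_VERSION, predict

DEFAULT_VOTE_THRESHOLD = 0.70
DEFAULT_TREE_GRID = (50, 100, 200, 500)
DEFAULT_DEPTH_GRID = (4, 8, 16, None)

_METRIC_FUNCS = {
    "accuracy": accuracy_score,
    "f1": lambda y, p: f1_score(y, p, average="macro", zero_division=0),
    "precision": lambda y, p: precision_score(y, p, average="macro", zero_division=0),
    "recall": lambda y, p: recall_score(y, p, average="macro", zero_division=0),
}
METRICS = tuple(_METRIC_FUNCS)


@dataclass
class RouterModel:
    forest: RandomForestClassifier
    classes: tuple[str, ...]
    vote_threshold: float = DEFAULT_VOTE_THRESHOLD
    split_seed: int = 0
    search_record: list[dict] = field(default_factory=list)
    test_accuracy: float = float("nan")
    full_accuracy: float = float("nan")
    train_index: np.ndarray | None = None
    test_index: np.ndarray | None = None
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        if not (0.0 < self.vote_threshold <= 1.0):
            raise ValueError("vote_threshold must lie in (0, 1]")

    def save(self, path) -> None:
        """Persist as a joblib archive: manifest dict + fitted forest."""
        manifest = {
            "schema_version": self.schema_version,
            "classes": list(self.classes),
            "vote_threshold": self.vote_threshold,
            "split_seed": self.split_seed,
            "search_record": self.search_record,
            "test_accuracy": self.test_accuracy,
            "full_accuracy": self.full_accuracy,
            "feature_columns": list(FEATURE_COLUMNS),
        }
        joblib.dump(
            {
                "manifest": manifest,
                "forest": self.forest,
                "train_index": self.train_index,
                "test_index": self.test_index,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "RouterModel":
        blob = joblib.load(path)
        m = blob["manifest"]
        return cls(
            forest=blob["forest"],
            classes=tuple(m["classes"]),
            vote_threshold=float(m["vote_threshold"]),
            split_seed=int(m["split_seed"]),
            search_record=m.get("search_record", []),
            test_accuracy=float(m.get("test_accuracy", float("nan"))),
            full_accuracy=float(m.get("full_accuracy", float("nan"))),
            train_index=blob.get("train_index"),
            test_index=blob.get("test_index"),
            schema_version=int(m.get("schema_version", SCHEMA_VERSION)),
        )


def _features(table: pd.DataFrame) -> np.ndarray:
    return table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)


def train_router(
    table: pd.DataFrame,
    vote_threshold: float = DEFAULT_VOTE_THRESHOLD,
    tree_grid=DEFAULT_TREE_GRID,
    depth_grid=DEFAULT_DEPTH_GRID,
    seed: int = 0,
    test_size: float = 0.2,
) -> RouterModel:
    """Grid-search and train the superset classifier.

    Requires a labelled table with at least two classes and 20 rows.
    The split is stratified by class; the seed fixes both the split and
    every forest, so repeated runs are identical.
    """
    labelled = table[table["superset"].notna()].reset_index(drop=True)
    y = labelled["superset"].astype(str).to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("router training needs at least two reaction classes")
    if len(labelled) < 20:
        raise ValueError(f"router training needs >= 20 rows, got {len(labelled)}")
    X = _features(labelled)

    idx = np.arange(len(labelled))
    idx_tr, idx_te = train_test_split(idx, test_size=test_size, random_state=seed, stratify=y)
    X_tr, X_te, y_tr, y_te = X[idx_tr], X[idx_te], y[idx_tr], y[idx_te]

    record = []
    best = None
    for n_trees in tree_grid:
        for depth in depth_grid:
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                max_depth=depth,
                criterion="gini",
                random_state=seed,
                n_jobs=1,
            )
            clf.fit(X_tr, y_tr)
            acc = accuracy_score(y_te, clf.predict(X_te))
            record.append({"n_trees": n_trees, "max_depth": depth, "test_accuracy": float(acc)})
            # ties go to the smaller forest, then the shallower tree
            key = (-acc, n_trees, np.inf if depth is None else depth)
            if best is None or key < best[0]:
                best = (key, clf, acc)

    _, forest, test_acc = best
    full_acc = accuracy_score(y, forest.predict(X))
    return RouterModel(
        forest=forest,
        classes=tuple(forest.classes_),
        vote_threshold=vote_threshold,
        split_seed=seed,
        search_record=record,
        test_accuracy=float(test_acc),
        full_accuracy=float(full_acc),
        train_index=idx_tr,
        test_index=idx_te,
    )


def _vote_counts(router: RouterModel, X: np.ndarray) -> np.ndarray:
    """Per-class tree-vote counts, shape (n_rows, n_classes)."""
    forest = router.forest
    n_classes = len(forest.classes_)
    counts = np.zeros((X.shape[0], n_classes), dtype=int)
    for est in forest.estimators_:
        pred = est.predict(X)
        # estimators are trained on encoded labels 0..k-1
        counts[np.arange(X.shape[0]), pred.astype(int)] += 1
    return counts


def vote_fraction(router: RouterModel, row: pd.DataFrame | np.ndarray) -> tuple[str, float]:
    """Winning class and the fraction of trees voting for it.

    Ties between classes with equal votes break alphabetically.
    """
    if isinstance(row, pd.DataFrame):
        X = _features(row)
    else:
        X = np.atleast_2d(np.asarray(row, dtype=float))
    if X.shape[0] != 1:
        raise ValueError("vote_fraction takes a single row")
    counts = _vote_counts(router, X)[0]
    order = np.argsort(router.forest.classes_)  # alphabetical tie-break
    sorted_classes = router.forest.classes_[order]
    sorted_counts = counts[order]
    winner_pos = int(np.argmax(sorted_counts))  # argmax keeps the first (alphabetical) max
    total = len(router.forest.estimators_)
    return str(sorted_classes[winner_pos]), float(sorted_counts[winner_pos]) / total


def route_predict(
    router: RouterModel, library: ModelLibrary, row: pd.DataFrame
) -> tuple[float, str, float]:
    """Predict one reaction's corrected energy through the router.

    Returns ``(energy, chosen_model_label, vote_fraction)``.  The label
    is the class name when the specialised model is used, ``"FULL"``
    when the vote is below threshold or the class has no model.
    """
    label, frac = vote_fraction(router, row)
    if frac >= router.vote_threshold and label in library.superset_models:
        model, used = library.superset_models[label], label
    else:
        model, used = library.full_model, "FULL"
    energy = float(predict(model, row)[0])
    return energy, used, frac


def route_predict_table(
    router: RouterModel, library: ModelLibrary, table: pd.DataFrame
) -> pd.DataFrame:
    """Vectorised routing over a feature table.

    Returns a frame with columns ``prediction``, ``chosen_model`` and
    ``vote_fraction`` aligned with the input rows.
    """
    X = _features(table)
    counts = _vote_counts(router, X)
    order = np.argsort(router.forest.classes_)
    sorted_classes = router.forest.classes_[order]
    sorted_counts = counts[:, order]
    winner_pos = np.argmax(sorted_counts, axis=1)
    total = len(router.forest.estimators_)
    labels = sorted_classes[winner_pos]
    fracs = sorted_counts[np.arange(len(table)), winner_pos] / total

    preds = np.empty(len(table))
    chosen = np.empty(len(table), dtype=object)
    full_preds = predict(library.full_model, table)
    preds[:] = full_preds
    chosen[:] = "FULL"
    for cls, model in library.superset_models.items():
        mask = (labels == cls) & (fracs >= router.vote_threshold)
        if mask.any():
            preds[mask] = predict(model, table[mask])
            chosen[mask] = cls
    return pd.DataFrame(
        {"prediction": preds, "chosen_model": chosen, "vote_fraction": fracs},
        index=table.index,
    )


@dataclass
class ImportanceReport:
    """Permutation importances: (feature, metric, subset) -> mean, sd."""

    n_rounds: int
    entries: list[dict]  # feature, metric, subset, mean, sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature", "metric", "subset", "mean", "sd"])

    def ranking(self, metric: str, subset: str = "test") -> list[str]:
        rows = [e for e in self.entries if e["metric"] == metric and e["subset"] == subset]
        return [e["feature"] for e in sorted(rows, key=lambda e: -e["mean"])]

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def permutation_importance(
    router: RouterModel,
    table: pd.DataFrame,
    n_rounds: int = 30,
    seed: int = 0,
    subsets: tuple[str, ...] = ("train", "test"),
) -> ImportanceReport:
    """Mean metric drop when each descriptor column is shuffled.

    For each feature and each of accuracy / macro-F1 / macro-precision /
    macro-recall: baseline metric minus the metric after permuting that
    single column, averaged over ``n_rounds`` shuffles.  Computed
    separately on the training and test subsets of the router's split
    (falling back to the whole table if the split indices are absent).
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    labelled = table[table["superset"].notna()].reset_index(drop=True)
    X_all = _features(labelled)
    y_all = labelled["superset"].astype(str).to_numpy()
    rng = np.random.default_rng(seed)

    subset_data = {}
    for name in subsets:
        idx = router.train_index if name == "train" else router.test_index
        if idx is None:
            subset_data[name] = (X_all, y_all)
        else:
            subset_data[name] = (X_all[idx], y_all[idx])

    entries = []
    for subset_name, (X, y) in subset_data.items():
        baseline_pred = router.forest.predict(X)
        baseline = {m: f(y, baseline_pred) for m, f in _METRIC_FUNCS.items()}
        for j, feature in enumerate(FEATURE_COLUMNS):
            drops = {m: np.empty(n_rounds) for m in METRICS}
            for r in range(n_rounds):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(len(X)), j]
                pred = router.forest.predict(Xp)
                for m, f in _METRIC_FUNCS.items():
                    drops[m][r] = baseline[m] - f(y, pred)
            for m in METRICS:
                entries.append(
                    {
                        "feature": feature,
                        "metric": m,
                        "subset": subset_name,
                        "mean": float(np.mean(drops[m])),
                        "sd": float(np.std(drops[m])),
                    }
                )
    return ImportanceReport(n_rounds=n_rounds, entries=entries)
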