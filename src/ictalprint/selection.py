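"""Gini-importance feature selection with a cross-validated forest grid.

A Random Forest is trained to separate ictal periods between persons
(one row per ictal period, person id as the class label) under 5-fold
cross-validation over a 3x3 hyperparameter grid: number of trees in
{25, 50, 100} x minimum samples to split a node in {2, 4, 6}, nine
settings in total. The best grid point by mean fold accuracy (ties
resolved toward fewer trees, then smaller min-split) is refit on all
ictal rows, its impurity-based (Gini) feature importances are
extracted, and the five most important features become the reduced
feature space — the candidate ictal fingerprint.

Trees are scale-invariant, so no feature scaling happens here;
Z-scoring is applied downstream for visualization and distances only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, KFold

from .features import METADATA_COLUMNS

__all__ = ["SelectionConfig", "ReducedFeatureSpace", "select_features", "reduce_table"]


@dataclass
class SelectionConfig:
    """Grid, folds and seed of the feature-selection stage."""

    n_trees_grid: tuple[int, ...] = (25, 50, 100)
    min_split_grid: tuple[int, ...] = (2, 4, 6)
    n_folds: int = 5
    n_selected: int = 5
    seed: int = 0
    fold_strategy: str = "stratified_by_person"   # | "plain"
    # remaining forest hyperparameters pinned so results do not drift
    # with library defaults
    criterion: str = "gini"
    max_features: str = "sqrt"
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if not self.n_trees_grid or not self.min_split_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.fold_strategy not in ("stratified_by_person", "plain"):
            raise ValueError(f"unknown fold strategy {self.fold_strategy!r}")

    @property
    def grid(self) -> list[tuple[int, int]]:
        return [(t, s) for t in self.n_trees_grid for s in self.min_split_grid]


@dataclass
class ReducedFeatureSpace:
    """Outcome of the selection stage."""

    selected: list[str]
    importances: dict[str, float]            # full catalog, best refit model
    best_hyperparams: tuple[int, int]        # (n_trees, min_split)
    cv_scores: dict[tuple[int, int], float]  # mean fold accuracy per grid point

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "selected": self.selected,
            "importances": {k: float(v) for k, v in self.importances.items()},
            "best_hyperparams": {"n_trees": self.best_hyperparams[0],
                                 "min_split": self.best_hyperparams[1]},
            "cv_scores": {f"trees={t},min_split={s}": float(a)
                          for (t, s), a in sorted(self.cv_scores.items())},
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def select_features(table: pd.DataFrame, config: SelectionConfig) -> ReducedFeatureSpace:
    """Run the cross-validated grid search and pick the top features.

    ``table`` must contain only ictal rows (one per seizure). Fully
    deterministic given ``config.seed``. Constant feature columns are
    retained with zero importance (a warning is emitted).
    """
    ictal = table
    if "kind" in ictal.columns:
        non_ictal = (ictal["kind"] != "ictal").sum()
        if non_ictal:
            raise ValueError(f"selection expects ictal rows only; found {non_ictal} others")
    feats = _feature_columns(ictal)
    if config.n_selected > len(feats):
        raise ValueError(f"n_selected={config.n_selected} exceeds catalog size {len(feats)}")
    X = ictal[feats].to_numpy(dtype=float)
    y = ictal["person_id"].to_numpy()
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    persons, counts = np.unique(y, return_counts=True)
    if len(persons) < 2:
        raise ValueError("need at least 2 persons to separate")
    short = persons[counts < config.n_folds]
    if len(short):
        raise ValueError(
            f"persons {short.tolist()} have fewer rows than n_folds={config.n_folds}; "
            "reduce n_folds or add seizures"
        )
    const = [f for f, v in zip(feats, X.var(axis=0)) if v == 0.0]
    if const:
        warnings.warn(f"constant feature columns retained with zero importance: {const}",
                      stacklevel=2)

    if config.fold_strategy == "stratified_by_person":
        splitter = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                                   random_state=config.seed)
    else:
        splitter = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    folds = list(splitter.split(X, y))

    def make_forest(n_trees: int, min_split: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_trees,
            min_samples_split=min_split,
            criterion=config.criterion,
            max_features=config.max_features,
            bootstrap=config.bootstrap,
            random_state=config.seed,
            n_jobs=1,
        )

    cv_scores: dict[tuple[int, int], float] = {}
    for n_trees, min_split in config.grid:
        accs = []
        for train, test in folds:
            clf = make_forest(n_trees, min_split)
            clf.fit(X[train], y[train])
            accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
        cv_scores[(n_trees, min_split)] = float(np.mean(accs))

    # best accuracy; ties toward fewer trees, then smaller min_split
    best = min(cv_scores, key=lambda hp: (-cv_scores[hp], hp[0], hp[1]))

    final = make_forest(*best)
    final.fit(X, y)
    imp = final.feature_importances_
    importances = {f: float(v) for f, v in zip(feats, imp)}
    # top-n by importance; ties resolved by catalog (column) order
    order = sorted(range(len(feats)), key=lambda i: (-imp[i], i))
    selected = [feats[i] for i in order[: config.n_selected]]
    return ReducedFeatureSpace(
        selected=selected, importances=importances,
        best_hyperparams=best, cv_scores=cv_scores,
    )


def reduce_table(table: pd.DataFrame, space: ReducedFeatureSpace) -> pd.DataFrame:
    """Restrict a feature table to the selected columns (metadata kept).

    Works on tables of any period kind; idempotent.
    """
    missing = [f for f in space.selected if f not in table.columns]
    if missing:
        raise KeyError(f"selected features missing from table: {missing}")
    meta = [c for c in METADATA_COLUMNS if c in table.columns]
    return table[meta + list(space.selected)].copy()
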