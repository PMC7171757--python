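"""Random survival forest risk models.

One model is fitted per endpoint and per feature source (tumor features
vs. node features). Trees are grown with log-rank splitting; the predicted
risk of a patient is the ensemble mortality (the sum over the event-time
grid of the ensemble cumulative hazard), so higher risk means predicted
worse outcome. Hyperparameters (``max_features`` ~ mtry, and the minimum
terminal node size) are tuned by grid search with event-stratified
cross-validation maximizing the out-of-fold Harrell C-index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.ensemble import RandomSurvivalForest

from .errors import ConfigurationError
from .evaluation import harrell_cindex
from .selection import outcomes_to_surv

__all__ = ["DEFAULT_GRID", "RiskModel", "tune_rsf", "fit_rsf", "predict_risk"]

#: mtry options (fraction of features, or "sqrt") x minimum node size
DEFAULT_GRID: dict[str, tuple] = {
    "max_features": ("sqrt", 0.333, 1.0),
    "min_samples_leaf": (3, 6, 15),
}


@dataclass
class RiskModel:
    forest: RandomSurvivalForest
    features: list[str]
    hyperparameters: dict
    seed: int
    endpoint: str
    train_medians: pd.Series = field(default=None)

    def manifest(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "features": self.features,
            "hyperparameters": {k: v for k, v in self.hyperparameters.items()},
            "seed": self.seed,
        }


def _grid_points(grid: dict[str, tuple]) -> list[dict]:
    if not grid:
        raise ConfigurationError("hyperparameter grid is empty")
    keys = sorted(grid)
    return [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]


def tune_rsf(table: pd.DataFrame, outcomes: pd.DataFrame,
             grid: dict[str, tuple] | None = None, n_folds: int = 5,
             seed: int = 0, n_estimators: int = 1000,
             max_refolds: int = 20) -> tuple[dict, pd.DataFrame]:
    """Grid search over RSF hyperparameters with stratified CV.

    Folds are stratified by the event indicator; a folding in which some
    training fold has no events is redrawn with a new seed. Returns the
    winning grid point (highest mean out-of-fold C-index, ties broken by
    grid order) and the full score table for audit.
    """
    if n_folds < 2:
        raise ConfigurationError(f"n_folds must be >= 2, got {n_folds}")
    points = _grid_points(grid if grid is not None else DEFAULT_GRID)
    y = outcomes_to_surv(outcomes, table.index)
    events = y["event"].astype(int)
    if events.sum() == 0:
        raise ValueError("no events; cannot tune a survival model")

    fold_seed = seed
    for attempt in range(max_refolds):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        folds = list(skf.split(table.values, events))
        if all(y[tr]["event"].sum() > 0 for tr, _ in folds):
            break
        fold_seed += 1
    else:
        raise RuntimeError("could not build folds with events in every training part")

    rows = []
    for point in points:
        scores = []
        for tr, te in folds:
            forest = _make_forest(point, table.shape[1], n_estimators, seed)
            forest.fit(table.values[tr], y[tr])
            risk = forest.predict(table.values[te])
            c = harrell_cindex(risk, y[te]["time"], y[te]["event"])
            if not np.isnan(c):
                scores.append(c)
        rows.append({**point, "cv_cindex_mean": float(np.mean(scores)),
                     "cv_cindex_sd": float(np.std(scores)), "n_folds_scored": len(scores)})
    score_table = pd.DataFrame(rows)
    best_idx = int(score_table["cv_cindex_mean"].idxmax())
    best = {k: points[best_idx][k] for k in points[best_idx]}
    return best, score_table


def _make_forest(params: dict, n_features: int, n_estimators: int, seed: int) -> RandomSurvivalForest:
    mf = params.get("max_features", "sqrt")
    if isinstance(mf, float):
        mf = max(1, int(round(mf * n_features))) / n_features
    return RandomSurvivalForest(
        n_estimators=n_estimators,
        max_features=mf,
        min_samples_leaf=int(params.get("min_samples_leaf", 3)),
        random_state=seed,
        n_jobs=1,
    )


def fit_rsf(table: pd.DataFrame, outcomes: pd.DataFrame, hyperparameters: dict,
            seed: int = 0, endpoint: str = "OS", n_estimators: int = 1000) -> RiskModel:
    """Fit the final forest on the full training table.

    The table must be complete (imputation happens upstream with
    training-set medians); a cohort without events is rejected.
    """
    if table.isna().any().any():
        bad = sorted(table.columns[table.isna().any()])
        raise ValueError(f"training table contains missing values in {bad}")
    y = outcomes_to_surv(outcomes, table.index)
    if y["event"].sum() == 0:
        raise ValueError("no events in training outcomes; cannot fit")
    forest = _make_forest(hyperparameters, table.shape[1], n_estimators, seed)
    forest.fit(table.values, y)
    return RiskModel(forest=forest, features=list(table.columns),
                     hyperparameters=dict(hyperparameters), seed=seed,
                     endpoint=endpoint, train_medians=table.median())


def predict_risk(model: RiskModel, table: pd.DataFrame) -> pd.Series:
    """Ensemble-mortality risk per patient (deterministic given the model).

    Missing feature values are imputed with the model's training medians;
    a missing feature *column* is an error naming it.
    """
    missing = [f for f in model.features if f not in table.columns]
    if missing:
        raise KeyError(f"table lacks model features: {missing}")
    x = table[model.features].fillna(model.train_medians)
    risk = model.forest.predict(x.values)
    if not np.all(np.isfinite(risk)):
        raise RuntimeError("forest produced non-finite risks")
    return pd.Series(risk, index=table.index, name=f"risk_{model.endpoint}")
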