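"""Ecological niche model fitting: collinearity screen, disk pseudo-absences,
case weighting, and boosted-regression-tree tuning.

The model is a presence / pseudo-absence classifier fitted with gradient
boosting (Bernoulli deviance). Pseudo-absences are drawn from an annulus
around the presences — far enough (below by the species' maximum daily
foraging transit) that they are unlikely to be false absences, close enough
that the contrast is ecologically meaningful. Presences and pseudo-absences
receive equal total weight, and hyperparameters are chosen by minimizing
cross-validated RMSE of the predicted probability against the 0/1 label.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import KFold

from .geo import cross_haversine_km
from .grids import RasterGrid
from .occurrences import OccurrenceSet

__all__ = [
    "TrainingTable",
    "TuningGrid",
    "FittedENM",
    "vif_select",
    "sample_disk_pseudoabsences",
    "assign_case_weights",
    "build_training_table",
    "tune_and_fit",
]


# ------------------------------------------------------------------ VIF step
def vif_select(table: pd.DataFrame, threshold: float = 10.0):
    """Iteratively drop the predictor with the largest variance inflation
    factor until every remaining VIF falls below ``threshold``.

    VIF_j = 1 / (1 - R²_j), with R²_j from an OLS regression of predictor j
    on all the others (plus intercept). A predictor whose VIF equals the
    threshold is removed (the criterion is ``VIF >= threshold``); perfectly
    collinear predictors surface as infinite VIF and go first.

    Returns ``(retained_names, trace)`` where ``trace`` is a list of dicts
    ``{"removed": name, "vif": value, "vifs": {name: vif, ...}}`` per step,
    with a final entry (``removed=None``) holding the VIFs of the kept set.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors")
    if len(table) <= len(cols):
        raise ValueError("need more rows than predictors")
    X = table.to_numpy(dtype=float)
    trace = []
    active = list(range(X.shape[1]))
    while True:
        vifs = {cols[j]: _vif(X, active, j) for j in active}
        worst = max(active, key=lambda j: vifs[cols[j]])
        if len(active) > 1 and vifs[cols[worst]] >= threshold:
            trace.append({"removed": cols[worst], "vif": vifs[cols[worst]], "vifs": dict(vifs)})
            active.remove(worst)
        else:
            trace.append({"removed": None, "vif": None, "vifs": dict(vifs)})
            break
    return [cols[j] for j in active], trace


def _vif(X: np.ndarray, active: list[int], j: int) -> float:
    others = [k for k in active if k != j]
    if not others:
        return 1.0
    y = X[:, j]
    A = np.column_stack([np.ones(len(y))] + [X[:, k] for k in others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


# -------------------------------------------------------- pseudo-absence disk
def eligible_pseudoabsence_cells(
    occ: OccurrenceSet, domain: RasterGrid, r_min_km: float = 130.0, r_max_km: float = 250.0
):
    """(rows, cols) of valid cells whose great-circle distance to the NEAREST
    presence lies within [r_min_km, r_max_km]."""
    if not r_min_km < r_max_km:
        raise ValueError("r_min_km must be below r_max_km")
    valid = domain.mask
    rows, cols = np.nonzero(valid)
    lons, lats = domain.cell_centers()
    cell_lons = lons[cols]
    cell_lats = lats[rows]
    d = cross_haversine_km(cell_lons, cell_lats, occ.lons, occ.lats)
    nearest = d.min(axis=1)
    keep = (nearest >= r_min_km) & (nearest <= r_max_km)
    return rows[keep], cols[keep]


def sample_disk_pseudoabsences(
    occ: OccurrenceSet,
    domain: RasterGrid,
    n: int = 5000,
    r_min_km: float = 130.0,
    r_max_km: float = 250.0,
    seed: int = 0,
):
    """Uniformly sample ``n`` pseudo-absence cell centers from the eligible
    annulus (no replacement).

    If fewer than ``n`` cells are eligible, all of them are returned with a
    warning — pseudo-absences are never duplicated.

    Returns a DataFrame with columns ``lon, lat, row, col``.
    """
    rows, cols = eligible_pseudoabsence_cells(occ, domain, r_min_km, r_max_km)
    if len(rows) == 0:
        raise ValueError("no cells eligible for pseudo-absence sampling")
    rng = np.random.default_rng([seed, 11])
    if len(rows) < n:
        warnings.warn(
            f"only {len(rows)} eligible cells for {n} requested pseudo-absences; returning all"
        )
        take = np.arange(len(rows))
    else:
        take = rng.choice(len(rows), size=n, replace=False)
    lons, lats = domain.cell_centers()
    return pd.DataFrame(
        {"lon": lons[cols[take]], "lat": lats[rows[take]], "row": rows[take], "col": cols[take]}
    )


# ---------------------------------------------------------------- case weights
@dataclass
class TrainingTable:
    """Presence / pseudo-absence cases with predictor values and case weights."""

    X: pd.DataFrame  # predictor values, one column per predictor
    y: np.ndarray  # 1 = presence, 0 = pseudo-absence
    weights: np.ndarray
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.X.to_numpy(dtype=float)).all():
            raise ValueError("non-finite predictor values in training table")

    @property
    def predictor_names(self) -> list[str]:
        return list(self.X.columns)


def assign_case_weights(table: TrainingTable) -> TrainingTable:
    """Pseudo-absences get weight 1; presences get n_absences / n_presences,
    so both classes carry the same total weight."""
    n_pres = int((table.y == 1).sum())
    n_abs = int((table.y == 0).sum())
    if n_pres == 0:
        raise ValueError("no presences in training table")
    if n_abs == 0:
        raise ValueError("no pseudo-absences in training table")
    w = np.where(table.y == 1, n_abs / n_pres, 1.0)
    return TrainingTable(X=table.X, y=table.y, weights=w, lon=table.lon, lat=table.lat)


def extract_stack_values(stack: Sequence[RasterGrid], names: Sequence[str], lons, lats) -> pd.DataFrame:
    """Predictor values at point locations (cells containing the points)."""
    data = {}
    for name, grid in zip(names, stack):
        data[name] = grid.value_at(np.asarray(lons), np.asarray(lats))
    return pd.DataFrame(data)


def build_training_table(
    occ: OccurrenceSet,
    pa: pd.DataFrame,
    stack: Sequence[RasterGrid],
    names: Sequence[str],
) -> TrainingTable:
    """Assemble and weight the presence / pseudo-absence table from a stack."""
    lons = np.concatenate([occ.lons, pa["lon"].to_numpy()])
    lats = np.concatenate([occ.lats, pa["lat"].to_numpy()])
    X = extract_stack_values(stack, names, lons, lats)
    y = np.concatenate([np.ones(len(occ), dtype=int), np.zeros(len(pa), dtype=int)])
    keep = np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    table = TrainingTable(
        X=X.loc[keep].reset_index(drop=True),
        y=y[keep],
        weights=np.ones(int(keep.sum())),
        lon=lons[keep],
        lat=lats[keep],
    )
    return assign_case_weights(table)


# ----------------------------------------------------------------- model tuning
@dataclass
class TuningGrid:
    """Hyperparameter grid for the boosted-tree search.

    Defaults reproduce the first published tuning matrix: shrinkage
    {0.01, 0.1, 0.3} × interaction depth {1, 3, 5} × minimum node size
    {5, 10, 15} × bag fraction {0.65, 0.8, 1}; the tree count is selected
    along the boosting path up to ``n_trees_max``.
    """

    shrinkage: Sequence[float] = (0.01, 0.1, 0.3)
    interaction_depth: Sequence[int] = (1, 3, 5)
    min_obs_in_node: Sequence[int] = (5, 10, 15)
    bag_fraction: Sequence[float] = (0.65, 0.8, 1.0)
    n_trees_max: int = 20000
    train_fraction: float = 0.8
    cv_folds: int = 10

    def __post_init__(self):
        for name in ("shrinkage", "interaction_depth", "min_obs_in_node", "bag_fraction"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def combinations(self):
        return list(
            itertools.product(self.shrinkage, self.interaction_depth, self.min_obs_in_node, self.bag_fraction)
        )


@dataclass
class FittedENM:
    """A tuned boosted-tree presence model."""

    model: GradientBoostingClassifier
    best_params: dict
    rmse: float
    predictor_names: list[str]
    cv_table: pd.DataFrame  # per-combination CV RMSE and optimal tree count
    training: Optional[TrainingTable] = None

    def predict_table(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of presence for rows of predictor values."""
        return self.model.predict_proba(X[self.predictor_names].to_numpy(dtype=float))[:, 1]

    def decision_table(self, X: pd.DataFrame) -> np.ndarray:
        """Raw additive score (logit scale) for rows of predictor values."""
        return self.model.decision_function(X[self.predictor_names].to_numpy(dtype=float))


def cv_rmse_curve(
    table: TrainingTable, params: tuple, n_trees_max: int, cv_folds: int, seed: int
) -> np.ndarray:
    """Mean cross-validated RMSE of predicted probability per tree count.

    Index t of the returned array corresponds to an ensemble of t+1 trees.
    """
    shrinkage, depth, min_obs, bag = params
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    X = table.X.to_numpy(dtype=float)
    sse = np.zeros(n_trees_max)
    n_val = 0
    for fold, (tr, va) in enumerate(kf.split(X)):
        clf = GradientBoostingClassifier(
            learning_rate=shrinkage,
            max_depth=depth,
            min_samples_leaf=min_obs,
            subsample=bag,
            n_estimators=n_trees_max,
            random_state=seed + fold,
        )
        clf.fit(X[tr], table.y[tr], sample_weight=table.weights[tr])
        for t, proba in enumerate(clf.staged_predict_proba(X[va])):
            sse[t] += np.sum((proba[:, 1] - table.y[va]) ** 2)
        n_val += len(va)
    return np.sqrt(sse / n_val)


def tune_and_fit(table: TrainingTable, grid: TuningGrid, seed: int = 0) -> FittedENM:
    """Grid search minimizing cross-validated RMSE; ties broken by fewer
    trees, then smaller shrinkage.

    For every hyperparameter combination the CV RMSE is evaluated along the
    whole boosting path and the path-optimal tree count is kept, so a single
    fit per fold covers every candidate ensemble size. The winning
    combination is refitted on the full table at its optimal tree count.
    """
    combos = grid.combinations()
    records = []
    for params in combos:
        curve = cv_rmse_curve(table, params, grid.n_trees_max, grid.cv_folds, seed)
        best_t = int(np.argmin(curve))
        records.append(
            {
                "shrinkage": params[0],
                "interaction_depth": params[1],
                "min_obs_in_node": params[2],
                "bag_fraction": params[3],
                "n_trees": best_t + 1,
                "cv_rmse": float(curve[best_t]),
            }
        )
    cv_table = pd.DataFrame(records)
    order = cv_table.sort_values(
        ["cv_rmse", "n_trees", "shrinkage"], kind="mergesort"
    ).index
    best = cv_table.loc[order[0]]
    model = GradientBoostingClassifier(
        learning_rate=best["shrinkage"],
        max_depth=int(best["interaction_depth"]),
        min_samples_leaf=int(best["min_obs_in_node"]),
        subsample=best["bag_fraction"],
        n_estimators=int(best["n_trees"]),
        random_state=seed,
    )
    model.fit(table.X.to_numpy(dtype=float), table.y, sample_weight=table.weights)
    return FittedENM(
        model=model,
        best_params={
            "shrinkage": float(best["shrinkage"]),
            "interaction_depth": int(best["interaction_depth"]),
            "min_obs_in_node": int(best["min_obs_in_node"]),
            "bag_fraction": float(best["bag_fraction"]),
            "n_trees": int(best["n_trees"]),
        },
        rmse=float(best["cv_rmse"]),
        predictor_names=table.predictor_names,
        cv_table=cv_table,
        training=table,
    )
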