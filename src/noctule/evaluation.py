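"""Model evaluation: continuous Boyce index, residual spatial correlograms,
variable contributions, Friedman's H interaction statistic, and marginal
response curves.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.inspection import permutation_importance

from .enm import FittedENM
from .geo import pairwise_haversine_km

__all__ = [
    "evaluate_boyce",
    "residual_correlogram",
    "variable_contributions",
    "interaction_strength",
    "marginal_response",
]


# -------------------------------------------------------------- Boyce index
def evaluate_boyce(
    presence_pred: Sequence[float],
    background_pred: Sequence[float],
    n_windows: int = 101,
    window_width_fraction: float = 0.1,
) -> float:
    """Continuous Boyce index of a presence-only suitability model.

    Moving windows of width ``window_width_fraction`` of the prediction
    range slide across the suitability axis; each window contributes the
    predicted-to-expected ratio P/E = (share of presence predictions in the
    window) / (share of background predictions in the window). The index is
    the Spearman rank correlation between P/E and the window midpoint, in
    [-1, 1]: values near +1 mean presences concentrate where suitability is
    high. Windows with zero expected share are skipped.

    Raises ``ValueError`` for constant predictions (the correlation is
    undefined).
    """
    p = np.asarray(presence_pred, dtype=float)
    b = np.asarray(background_pred, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background predictions must be non-empty")
    lo, hi = float(b.min()), float(b.max())
    lo = min(lo, float(p.min()))
    hi = max(hi, float(p.max()))
    if hi - lo <= 0:
        raise ValueError("constant predictions: Boyce index undefined")
    width = window_width_fraction * (hi - lo)
    mids = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    pe, used_mids = [], []
    for m in mids:
        w0, w1 = m - width / 2, m + width / 2
        fp = np.mean((p >= w0) & (p <= w1))
        fb = np.mean((b >= w0) & (b <= w1))
        if fb == 0:
            continue
        pe.append(fp / fb)
        used_mids.append(m)
    if len(pe) < 3:
        raise ValueError("too few usable windows for the Boyce index")
    rho, _ = spearmanr(used_mids, pe)
    if np.isnan(rho):
        raise ValueError("Boyce correlation undefined (constant P/E)")
    return float(rho)


# ------------------------------------------------------------- correlogram
def residual_correlogram(
    residuals: Sequence[float],
    lons: Sequence[float],
    lats: Sequence[float],
    n_classes: int = 10,
    n_permutations: int = 199,
    seed: int = 0,
) -> list[dict]:
    """Moran's I of residuals per great-circle distance class.

    Distance classes are equal-width from 0 to the maximum pairwise
    distance. Within a class, binary weights w_ij = 1 link pairs whose
    distance falls inside it, and

        I = (n / sum W) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2)

    with z the centered residuals. A permutation p-value (two-sided on |I|)
    comes from shuffling residuals over locations. Classes with no pairs are
    reported with ``moran_i=None``.
    """
    z = np.asarray(residuals, dtype=float)
    n = z.size
    if n < 10:
        raise ValueError("need at least 10 points for a correlogram")
    z = z - z.mean()
    d = pairwise_haversine_km(lons, lats)
    iu = np.triu_indices(n, k=1)
    dmax = d[iu].max()
    edges = np.linspace(0.0, dmax, n_classes + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    rng = np.random.default_rng([seed, 17])
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    denom = float(z @ z)
    out = []
    for k in range(n_classes):
        w = (d >= edges[k]) & (d < edges[k + 1])
        np.fill_diagonal(w, False)
        s0 = w.sum()
        if s0 == 0:
            out.append({"mean_distance_km": None, "moran_i": None, "p_value": None, "n_pairs": 0})
            continue
        mean_dist = float(d[w].mean())
        W = w.astype(float)
        obs = (n / s0) * float(z @ (W @ z)) / denom
        zp = z[perms]  # (n_perm, n)
        perm_i = (n / s0) * np.einsum("pi,ij,pj->p", zp, W, zp) / denom
        p = (np.sum(np.abs(perm_i) >= abs(obs)) + 1) / (n_permutations + 1)
        out.append(
            {
                "mean_distance_km": mean_dist,
                "moran_i": float(obs),
                "p_value": float(p),
                "n_pairs": int(s0 // 2),
            }
        )
    return out


# ------------------------------------------------------------ contributions
def variable_contributions(model: FittedENM, method: str = "impurity", seed: int = 0) -> dict[str, float]:
    """Relative contribution of each predictor, in percent summing to 100.

    ``method='impurity'`` attributes the per-split reduction in deviance
    across the ensemble; ``method='permutation'`` instead measures the drop
    in weighted accuracy when a predictor is shuffled (slower, less biased
    for correlated predictors).
    """
    names = model.predictor_names
    if method == "impurity":
        raw = np.asarray(model.model.feature_importances_, dtype=float)
    elif method == "permutation":
        if model.training is None:
            raise ValueError("permutation contributions need the stored training table")
        res = permutation_importance(
            model.model,
            model.training.X.to_numpy(dtype=float),
            model.training.y,
            n_repeats=5,
            random_state=seed,
        )
        raw = np.clip(res.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown method {method!r}")
    total = raw.sum()
    if total <= 0:
        warnings.warn("model attributes no importance to any predictor")
        raw = np.ones_like(raw)
        total = raw.sum()
    return {name: float(100.0 * v / total) for name, v in zip(names, raw)}


# --------------------------------------------------- interaction / response
def _quantile_grid(x: np.ndarray, grid_points: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, grid_points)
    return np.unique(np.quantile(x, qs))


def _partial_dependence(model: FittedENM, X: np.ndarray, cols: list[int], grid: list[np.ndarray]) -> np.ndarray:
    """Centered partial dependence of the raw (logit-scale) score on ``cols``."""
    shape = [len(g) for g in grid]
    pd_vals = np.zeros(shape)
    Xw = X.copy()
    for idx in np.ndindex(*shape):
        for c, g, i in zip(cols, grid, idx):
            Xw[:, c] = g[i]
        pd_vals[idx] = model.model.decision_function(Xw).mean()
    return pd_vals - pd_vals.mean()


def interaction_strength(model: FittedENM, pair: tuple[str, str], grid_points: int = 50) -> float:
    """Friedman's H statistic for a predictor pair (0 = purely additive).

    H² = sum [PD_jk - PD_j - PD_k]² / sum PD_jk² over a quantile grid of the
    two predictors, with centered partial-dependence functions on the raw
    score scale; the square root is returned.
    """
    if model.training is None:
        raise ValueError("interaction_strength needs the stored training table")
    names = model.predictor_names
    j, k = (names.index(pair[0]), names.index(pair[1]))
    X = model.training.X.to_numpy(dtype=float)
    gj = _quantile_grid(X[:, j], grid_points)
    gk = _quantile_grid(X[:, k], grid_points)
    pd_jk = _partial_dependence(model, X, [j, k], [gj, gk])
    pd_j = _partial_dependence(model, X, [j], [gj])
    pd_k = _partial_dependence(model, X, [k], [gk])
    resid = pd_jk - pd_j[:, None] - pd_k[None, :]
    denom = np.sum(pd_jk**2)
    if denom <= 1e-12:
        return 0.0
    return float(np.sqrt(max(0.0, np.sum(resid**2) / denom)))


def marginal_response(model: FittedENM, predictor: str, grid_points: int = 100) -> pd.DataFrame:
    """Partial-dependence curve of predicted probability over one predictor.

    The predictor sweeps its observed range while the others keep their
    training distribution; each grid value reports the mean predicted
    probability.
    """
    if model.training is None:
        raise ValueError("marginal_response needs the stored training table")
    names = model.predictor_names
    j = names.index(predictor)
    X = model.training.X.to_numpy(dtype=float)
    grid = np.linspace(X[:, j].min(), X[:, j].max(), grid_points)
    preds = np.empty(grid_points)
    Xw = X.copy()
    for i, v in enumerate(grid):
        Xw[:, j] = v
        preds[i] = model.model.predict_proba(Xw)[:, 1].mean()
    return pd.DataFrame({"value": grid, "partial_prediction": preds})
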