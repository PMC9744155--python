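"""Projection of the fitted model over raster stacks, extrapolation
diagnostics (MESS), MESS-weighted multi-GCM combination (MEDI), and the
1-to-10 suitability reclassification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .enm import FittedENM
from .grids import RasterGrid

__all__ = [
    "SuitabilityMap",
    "MessMap",
    "project_model",
    "compute_mess",
    "combine_medi",
    "reclassify_suitability",
]

Scenario = Union[str, tuple[str, int, str]]


@dataclass
class SuitabilityMap:
    """Predicted suitability in [0, 1] for one scenario."""

    grid: RasterGrid
    scenario: Scenario = "current"


@dataclass
class MessMap:
    """Multivariate environmental similarity of a projection surface to the
    calibration data; negative cells flag novel (extrapolated) conditions."""

    grid: RasterGrid
    reference_columns: list[str]


def project_model(model: FittedENM, stack: Sequence[RasterGrid], names: Sequence[str], scenario: Scenario = "current") -> SuitabilityMap:
    """Per-cell probability prediction of the fitted model on a raster stack.

    ``names`` labels the stack layers; every model predictor must be
    present (extra layers are ignored). Nodata propagates.
    """
    layer = {}
    for name, grid in zip(names, stack):
        layer[name] = grid
    missing = [n for n in model.predictor_names if n not in layer]
    if missing:
        raise ValueError(f"stack is missing model predictor(s): {', '.join(missing)}")
    grids = [layer[n] for n in model.predictor_names]
    base = grids[0]
    valid = base.mask.copy()
    for g in grids[1:]:
        valid &= g.mask
    X = np.column_stack([g.values[valid] for g in grids])
    out = np.full(base.values.shape, np.nan)
    if valid.any():
        out[valid] = model.model.predict_proba(X)[:, 1]
    return SuitabilityMap(grid=base.like(out), scenario=scenario)


def mess_scores(reference: np.ndarray, probes: np.ndarray) -> np.ndarray:
    """MESS similarity of probe rows to a reference sample, per the standard
    piecewise formula.

    For each probe value p of one predictor, with f = percent of reference
    values strictly below p, min/max the reference extremes and the
    similarity s:

    * f = 0:        s = 100 * (p - min) / (max - min)
    * 0 < f <= 50:  s = 2 f
    * 50 < f < 100: s = 2 (100 - f)
    * f = 100:      s = 100 * (max - p) / (max - min)

    The MESS of a probe row is the minimum of s over predictors. Negative
    values occur only outside the reference range. A zero-variance reference
    predictor gets s = 0 at the constant and a machine-epsilon range
    otherwise (with a warning).
    """
    reference = np.asarray(reference, dtype=float)
    probes = np.asarray(probes, dtype=float)
    n_ref, n_pred = reference.shape
    s_all = np.empty((probes.shape[0], n_pred))
    for jcol in range(n_pred):
        ref = np.sort(reference[:, jcol])
        p = probes[:, jcol]
        rmin, rmax = ref[0], ref[-1]
        rng = rmax - rmin
        degenerate = rng == 0
        if degenerate:
            warnings.warn(f"zero-variance reference predictor (column {jcol})")
            rng = np.finfo(float).eps
        f = 100.0 * np.searchsorted(ref, p, side="left") / n_ref
        s = np.where(f <= 50.0, 2.0 * f, 2.0 * (100.0 - f))
        s = np.where(f == 0.0, 100.0 * (p - rmin) / rng, s)
        s = np.where(f == 100.0, 100.0 * (rmax - p) / rng, s)
        if degenerate:
            s = np.where(p == rmin, 0.0, s)
        s_all[:, jcol] = s
    return s_all.min(axis=1)


def compute_mess(reference: pd.DataFrame, stack: Sequence[RasterGrid], names: Sequence[str]) -> MessMap:
    """MESS map of a projection stack against the calibration table.

    Only the reference columns (the predictors the model uses) are scored.
    """
    if len(reference) == 0:
        raise ValueError("empty reference table")
    layer = dict(zip(names, stack))
    missing = [c for c in reference.columns if c not in layer]
    if missing:
        raise ValueError(f"stack is missing reference predictor(s): {', '.join(missing)}")
    grids = [layer[c] for c in reference.columns]
    base = grids[0]
    valid = base.mask.copy()
    for g in grids[1:]:
        valid &= g.mask
    probes = np.column_stack([g.values[valid] for g in grids])
    out = np.full(base.values.shape, np.nan)
    if valid.any():
        out[valid] = mess_scores(reference.to_numpy(dtype=float), probes)
    return MessMap(grid=base.like(out), reference_columns=list(reference.columns))


def combine_medi(maps: Sequence[SuitabilityMap], mess_maps: Sequence[MessMap], eps: float = 1e-6) -> SuitabilityMap:
    """MESS-weighted convex combination of per-GCM projections.

    Each GCM's per-cell weight is its MESS clipped at zero plus a small
    floor ``eps``, so projections under novel (negative-MESS) conditions are
    suppressed but the combination stays defined when every GCM
    extrapolates. The output is tagged ``gcm="MEDI"``.
    """
    if len(maps) != len(mess_maps) or len(maps) == 0:
        raise ValueError("need one MESS map per suitability map")
    base = maps[0].grid
    for m in maps[1:]:
        if not m.grid.same_grid(base, check_mask=False):
            raise ValueError("suitability maps must share a grid")
    num = np.zeros(base.values.shape)
    den = np.zeros(base.values.shape)
    any_valid = np.zeros(base.values.shape, dtype=bool)
    for smap, mmap in zip(maps, mess_maps):
        s = smap.grid.values
        w = np.maximum(mmap.grid.values, 0.0) + eps
        ok = np.isfinite(s) & np.isfinite(w)
        num[ok] += (w * s)[ok]
        den[ok] += w[ok]
        any_valid |= ok
    out = np.full(base.values.shape, np.nan)
    out[any_valid] = num[any_valid] / den[any_valid]
    scenario = maps[0].scenario
    if isinstance(scenario, tuple):
        scenario = (scenario[0], scenario[1], "MEDI")
    return SuitabilityMap(grid=base.like(out), scenario=scenario)


def reclassify_suitability(smap: SuitabilityMap) -> RasterGrid:
    """Equal-interval reclassification of [0, 1] suitability to integers 1-10.

    Bin edges belong to the upper bin (0.10 -> class 2) except 1.0, which
    stays in class 10: v -> min(floor(10 v) + 1, 10).
    """
    v = smap.grid.values
    if np.nanmin(v) < 0 or np.nanmax(v) > 1:
        raise ValueError("suitability values must lie in [0, 1]")
    classes = np.minimum(np.floor(10.0 * v) + 1.0, 10.0)
    return smap.grid.like(np.where(np.isfinite(v), classes, np.nan))
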