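"""SVM-based bioclimatic niche-overlap tests and the protected-area gap
analysis.

Two groups of points "overlap" in environmental space when no decision
surface of the chosen family (hyperplane, or second-degree polynomial
surface) separates them perfectly — the criterion used by
perfect-separability niche tests. A near-hard-margin SVM (large
misclassification penalty) supplies the candidate surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from sklearn.svm import SVC

from .geo import cross_haversine_km
from .occurrences import OccurrenceSet
from .overlay import ForestPolygon
from .synth import ProtectedArea

__all__ = [
    "EnvPointSet",
    "OverlapMatrix",
    "svm_separability",
    "overlap_matrix",
    "gap_analysis",
    "forest_env_points",
]

HARD_MARGIN_C = 1e6
MIN_SET_SIZE = 3
#: libsvm iteration cap; with the near-hard margin the optimizer can cycle
#: indefinitely on inseparable data, and a capped imperfect fit already
#: implies the correct "overlap" verdict.
SVM_MAX_ITER = 200_000


@dataclass
class EnvPointSet:
    """Labelled rows of predictor values for one group of localities."""

    label: str
    points: np.ndarray  # (n, n_predictors)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))


@dataclass
class OverlapMatrix:
    """Symmetric pairwise separability verdicts among labelled groups."""

    labels: list[str]
    entries: dict[tuple[str, str], dict] = field(default_factory=dict)

    def verdict(self, a: str, b: str) -> Optional[str]:
        if a == b:
            return "overlap"
        entry = self.entries.get((a, b)) or self.entries.get((b, a))
        return entry["verdict"] if entry else None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.labels, columns=self.labels, dtype=object)
        for a in self.labels:
            for b in self.labels:
                out.loc[a, b] = self.verdict(a, b) or "untested"
        return out


def svm_separability(a: EnvPointSet, b: EnvPointSet, kernel: str = "linear", C: float = HARD_MARGIN_C) -> dict:
    """Perfect-separability verdict for two point clouds.

    Predictors are z-scored on the pooled set, then a two-class SVM with a
    near-hard margin (penalty ``C``) is fitted; ``non-overlap`` means the
    training points are classified with 100% accuracy. The ``poly2`` kernel
    is (gamma x.x' + 1)^2 with gamma = 1/n_predictors. Point clouds sharing
    an identical point are declared overlapping without fitting.
    """
    if kernel not in ("linear", "poly2"):
        raise ValueError("kernel must be 'linear' or 'poly2'")
    if a.points.size == 0 or b.points.size == 0:
        raise ValueError("both point sets must be non-empty")
    if a.points.shape[1] != b.points.shape[1]:
        raise ValueError("point sets must share predictor columns")
    shared = set(map(tuple, a.points)) & set(map(tuple, b.points))
    if shared:
        return {"verdict": "overlap", "n_support_vectors": 0, "kernel": kernel, "accuracy": None}
    X = np.vstack([a.points, b.points])
    y = np.concatenate([np.zeros(len(a.points)), np.ones(len(b.points))])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    if kernel == "linear":
        clf = SVC(kernel="linear", C=C, max_iter=SVM_MAX_ITER)
    else:
        clf = SVC(kernel="poly", degree=2, gamma=1.0 / X.shape[1], coef0=1.0, C=C, max_iter=SVM_MAX_ITER)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xz, y)
    acc = float(clf.score(Xz, y))
    return {
        "verdict": "non-overlap" if acc == 1.0 else "overlap",
        "n_support_vectors": int(clf.n_support_.sum()),
        "kernel": kernel,
        "accuracy": acc,
    }


def overlap_matrix(sets: Sequence[EnvPointSet], kernel: str = "linear") -> OverlapMatrix:
    """One-vs-one separability over every unordered pair of groups.

    Groups below the minimum size (3 points) are left untested with a
    warning.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 point sets")
    labels = [s.label for s in sets]
    mat = OverlapMatrix(labels=labels)
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if len(sets[i].points) < MIN_SET_SIZE or len(sets[j].points) < MIN_SET_SIZE:
                warnings.warn(
                    f"group pair ({labels[i]}, {labels[j]}) untested: below minimum size"
                )
                continue
            mat.entries[(labels[i], labels[j])] = svm_separability(sets[i], sets[j], kernel)
    return mat


def forest_env_points(
    forest: ForestPolygon, stack, names: Sequence[str]
) -> np.ndarray:
    """Predictor rows sampled within a refined forest polygon, one row per
    intersected raster cell (cell centers covered by the polygon); falls
    back to the center cell for sub-cell polygons."""
    base = stack[0]
    lons2d, lats2d = base.center_grids()
    minx, miny, maxx, maxy = forest.polygon.bounds
    cand = (lons2d >= minx - base.res) & (lons2d <= maxx + base.res) & (
        (lats2d >= miny - base.res) & (lats2d <= maxy + base.res)
    ) & base.mask
    rows_cols = [
        (r, c)
        for r, c in zip(*np.nonzero(cand))
        if forest.polygon.covers(Point(lons2d[r, c], lats2d[r, c]))
    ]
    if not rows_cols:
        r, c = base.index_of(*forest.center)
        if 0 <= r < base.nrows and 0 <= c < base.ncols and np.isfinite(base.values[r, c]):
            rows_cols = [(r, c)]
        else:
            return np.empty((0, len(names)))
    return np.array([[g.values[r, c] for g in stack] for r, c in rows_cols])


def gap_analysis(
    occ: OccurrenceSet,
    protected: Sequence[ProtectedArea],
    forests: Sequence[ForestPolygon],
    densify_deg: float = 0.01,
) -> pd.DataFrame:
    """Protection status and forest distance of every occurrence.

    Each record is tested for membership in Natura 2000 and nationally
    designated protected areas (a polygon of kind ``both`` counts as
    either; spatially overlapping polygons of the two kinds also yield
    ``both``), and its great-circle distance to the nearest forest polygon
    boundary is measured (0 inside a forest). Invalid polygons are repaired
    by a zero-width buffer with a warning.
    """
    import shapely

    natura, national = [], []
    for p in protected:
        poly = p.polygon
        if not poly.is_valid:
            warnings.warn("invalid protected polygon repaired with zero-width buffer")
            poly = poly.buffer(0)
        if p.kind in ("natura2000", "both"):
            natura.append(poly)
        if p.kind in ("national", "both"):
            national.append(poly)

    forest_coords = []
    for f in forests:
        if f.polygon.is_empty or f.polygon.area == 0:
            forest_coords.append(np.asarray([f.center]))
        else:
            forest_coords.append(shapely.get_coordinates(f.polygon.boundary.segmentize(densify_deg)))

    rows = []
    for rec in occ.records:
        pt = Point(rec.lon, rec.lat)
        in_nat = any(poly.covers(pt) for poly in natura)
        in_ndp = any(poly.covers(pt) for poly in national)
        protection = "both" if in_nat and in_ndp else "natura2000" if in_nat else "national" if in_ndp else "none"
        if forests:
            dists = []
            for f, coords in zip(forests, forest_coords):
                if f.polygon.covers(pt):
                    dists.append(0.0)
                else:
                    dists.append(
                        float(cross_haversine_km([rec.lon], [rec.lat], coords[:, 0], coords[:, 1]).min())
                    )
            dist = min(dists)
        else:
            dist = np.nan
        rows.append(
            {
                "lon": rec.lon,
                "lat": rec.lat,
                "group": rec.group,
                "protection": protection,
                "distance_to_nearest_forest_km": dist,
            }
        )
    return pd.DataFrame(rows)
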