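"""Synthetic landscapes with known ground truth.

The analyses in this package were designed for continental-scale climate
rasters, occurrence records, river networks, old-growth-forest points and
protected-area polygons. This module generates stand-ins for all of them
with the statistical structure the pipeline assumes — spatially
autocorrelated and partially collinear predictor surfaces, occurrences drawn
from a known logistic suitability function, per-GCM perturbed future
surfaces, a branching river network with connectivity attributes — together
with the ground truth needed for parameter-recovery tests.

Everything is deterministic under ``truth.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, mapping

from .grids import RasterGrid
from .occurrences import OccurrenceRecord, OccurrenceSet

__all__ = [
    "SyntheticTruth",
    "RiverSegment",
    "ForestSite",
    "ProtectedArea",
    "LandscapeBundle",
    "default_truth",
    "generate_environment",
    "sample_true_occurrences",
    "generate_rivers_forests_protected",
    "generate_landscape",
]

SSPS = ("ssp370", "ssp585")
YEARS = (2030, 2050, 2070)
DEFAULT_GCMS = ("gcm-a", "gcm-b", "gcm-c")
FOREST_CATEGORIES = ("Near-virgin Forest", "Old-Growth Forest", "Long Untouched Forest")
PROTECTED_KINDS = ("natura2000", "national", "both")

#: Stronger forcing under the high-emission pathway.
SSP_MULTIPLIER = {"ssp370": 1.0, "ssp585": 1.5}


@dataclass
class SyntheticTruth:
    """Ground truth controlling a synthetic landscape.

    ``beta`` acts on z-scored predictors through a logistic suitability
    ``p = expit(intercept + beta . z)``. ``gcm_shift`` maps a GCM label to a
    per-predictor additive trend per decade (predictor units); the trend is
    scaled by the decades elapsed since 2020 and by the SSP multiplier, so a
    zero shift leaves future surfaces identical to the current one up to the
    ``gcm_noise_sd`` spatial noise.
    """

    seed: int
    beta: np.ndarray
    intercept: float = 0.0
    collinear_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    gcm_shift: dict[str, np.ndarray] = field(default_factory=dict)
    gcm_noise_sd: dict[str, float] = field(default_factory=dict)
    smooth_sigma: float = 5.0
    nodata_fraction: float = 0.05

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        for i, j, rho in self.collinear_pairs:
            if not 0.0 <= abs(rho) <= 1.0:
                raise ValueError("collinearity targets must lie in [-1, 1]")
            if i == j:
                raise ValueError("collinear pair must involve two distinct predictors")

    @property
    def gcms(self) -> tuple[str, ...]:
        return tuple(self.gcm_shift) or DEFAULT_GCMS


def default_truth(seed: int, n_predictors: int = 6) -> SyntheticTruth:
    """Study-condition defaults: a dominant cold-limit predictor, two weaker
    effects, one strongly collinear pair, three GCMs with warming-like trends
    of increasing strength."""
    if n_predictors < 4:
        raise ValueError("default truth needs at least 4 predictors")
    beta = np.zeros(n_predictors)
    beta[:3] = (2.0, -1.2, 0.8)
    shifts = {}
    noise = {}
    for k, gcm in enumerate(DEFAULT_GCMS):
        s = np.zeros(n_predictors)
        s[0] = 0.15 * (k + 1)  # per-decade warming trend on the dominant predictor
        s[1] = -0.08 * (k + 1)
        shifts[gcm] = s
        noise[gcm] = 0.05
    return SyntheticTruth(
        seed=seed,
        beta=beta,
        intercept=-1.0,
        collinear_pairs=[(n_predictors - 2, n_predictors - 1, 0.95)],
        gcm_shift=shifts,
        gcm_noise_sd=noise,
    )


# --------------------------------------------------------------- environment
def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def _grid_shape(extent, resolution):
    xmin, ymin, xmax, ymax = extent
    ncols = int(round((xmax - xmin) / resolution))
    nrows = int(round((ymax - ymin) / resolution))
    if ncols < 1 or nrows < 1:
        raise ValueError(f"degenerate extent {extent!r} at resolution {resolution}: zero cells")
    return nrows, ncols


def generate_environment(
    extent: tuple[float, float, float, float],
    resolution: float,
    n_predictors: int,
    truth: SyntheticTruth,
    ssps: Sequence[str] = SSPS,
    years: Sequence[int] = YEARS,
):
    """Current predictor stack plus per-(ssp, year, gcm) future stacks.

    Each predictor is low-pass-filtered white noise plus a latitudinal
    gradient, z-scored over valid cells. Requested collinear pairs are
    imposed exactly by Gram–Schmidt over the valid cells, so the sample
    correlation equals the target. Future surfaces add the (scaled) GCM
    trend and smooth spatial noise of the configured standard deviation.

    Returns ``(current_stack, future_stacks)`` where ``future_stacks`` maps
    ``(ssp, year, gcm)`` to a predictor list on the same grid.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if n_predictors < 2:
        raise ValueError("need at least 2 predictors")
    nrows, ncols = _grid_shape(extent, resolution)
    xmin, ymin = extent[0], extent[1]
    rng = np.random.default_rng([truth.seed, 1])

    # shared nodata mask from an independent smooth field (an "ocean" blob)
    mask_field = _smooth_field(rng, (nrows, ncols), truth.smooth_sigma)
    if truth.nodata_fraction > 0:
        thresh = np.quantile(mask_field, truth.nodata_fraction)
        valid = mask_field > thresh
    else:
        valid = np.ones((nrows, ncols), dtype=bool)
    if not valid.any():
        raise ValueError("all-nodata landscape")

    lat_gradient = np.linspace(1.0, -1.0, nrows)[:, None] * np.ones((1, ncols))
    fields = []
    for p in range(n_predictors):
        base = _smooth_field(rng, (nrows, ncols), truth.smooth_sigma)
        slope = rng.uniform(-0.8, 0.8)
        f = base + slope * lat_gradient
        fields.append(_standardize(f, valid))

    for i, j, rho in truth.collinear_pairs:
        fields[j] = _impose_correlation(fields[i], fields[j], rho, valid)

    def _to_grid(arr):
        vals = np.where(valid, arr, np.nan)
        return RasterGrid(vals, xmin, ymin, resolution)

    current = [_to_grid(f) for f in fields]

    future: dict[tuple[str, int, str], list[RasterGrid]] = {}
    for ssp in ssps:
        for year in years:
            decades = (year - 2020) / 10.0
            for gcm in truth.gcms:
                shift = np.asarray(truth.gcm_shift.get(gcm, np.zeros(n_predictors)), dtype=float)
                sd = float(truth.gcm_noise_sd.get(gcm, 0.0))
                key_rng = np.random.default_rng(
                    [truth.seed, 2, ssps.index(ssp), int(year), list(truth.gcms).index(gcm)]
                )
                stack = []
                for p in range(n_predictors):
                    f = fields[p] + shift[p] * decades * SSP_MULTIPLIER.get(ssp, 1.0)
                    if sd > 0:
                        f = f + sd * _smooth_field(key_rng, (nrows, ncols), truth.smooth_sigma)
                    stack.append(_to_grid(f))
                future[(ssp, year, gcm)] = stack
    return current, future


def _standardize(f: np.ndarray, valid: np.ndarray) -> np.ndarray:
    mu = f[valid].mean()
    sd = f[valid].std()
    return (f - mu) / (sd + 1e-12)


def _impose_correlation(x: np.ndarray, q: np.ndarray, rho: float, valid: np.ndarray) -> np.ndarray:
    """Rebuild q so that corr(x, q) over valid cells equals rho exactly."""
    xv = x[valid] - x[valid].mean()
    qv = q[valid] - q[valid].mean()
    proj = (qv @ xv) / (xv @ xv)
    # residualize the full field with the valid-cell projection coefficients
    q_perp = (q - q[valid].mean()) - proj * (x - x[valid].mean())
    q_perp = _standardize(q_perp, valid)
    x_std = _standardize(x, valid)
    return rho * x_std + np.sqrt(max(0.0, 1.0 - rho**2)) * q_perp


# --------------------------------------------------------------- occurrences
def true_suitability(stack: Sequence[RasterGrid], truth: SyntheticTruth) -> RasterGrid:
    """Logistic suitability surface implied by the truth on a predictor stack."""
    from scipy.special import expit

    valid = stack[0].mask
    z = np.zeros(stack[0].values.shape)
    for p, grid in enumerate(stack):
        vals = grid.values
        mu = np.nanmean(vals)
        sd = np.nanstd(vals)
        z = z + truth.beta[p] * (np.where(valid, vals, 0.0) - mu) / (sd + 1e-12)
    suit = expit(truth.intercept + z)
    return stack[0].like(np.where(valid, suit, np.nan))


def sample_true_occurrences(
    stack: Sequence[RasterGrid],
    truth: SyntheticTruth,
    n: int,
    seed: int,
    year_range: tuple[int, int] = (1990, 2020),
) -> OccurrenceSet:
    """Draw n presence records with cell probability proportional to the
    true logistic suitability.

    Coordinates are jittered uniformly within the sampled cell (full
    precision, so default coordinate-precision filters keep every record);
    years are uniform in ``year_range`` and sources alternate between
    literature and GBIF.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    suit = true_suitability(stack, truth)
    valid = suit.mask
    if not valid.any():
        raise ValueError("all-nodata stack")
    rng = np.random.default_rng([seed, 3])
    probs = suit.values[valid]
    probs = probs / probs.sum()
    rows, cols = np.nonzero(valid)
    idx = rng.choice(len(rows), size=n, replace=True, p=probs)
    res = suit.res
    records = []
    for k, i in enumerate(idx):
        lon = suit.xmin + (cols[i] + rng.uniform(0.05, 0.95)) * res
        lat = suit.ymax - (rows[i] + rng.uniform(0.05, 0.95)) * res
        records.append(
            OccurrenceRecord(
                lon=float(lon),
                lat=float(lat),
                year=int(rng.integers(year_range[0], year_range[1] + 1)),
                source="literature" if k % 2 else "gbif",
            )
        )
    return OccurrenceSet(records=records)


# ------------------------------------------------- rivers, forests, protected
@dataclass(frozen=True)
class RiverSegment:
    """A river reach: polyline vertices (lon, lat) plus network attributes."""

    coords: tuple[tuple[float, float], ...]
    strahler_order: int
    csi: float  # Connectivity Status Index, percent
    urb: float  # urbanization pressure, percent


@dataclass(frozen=True)
class ForestSite:
    lon: float
    lat: float
    area_ha: float
    category: str


@dataclass(frozen=True)
class ProtectedArea:
    polygon: Polygon
    kind: str  # natura2000 | national | both


def generate_rivers_forests_protected(
    extent: tuple[float, float, float, float],
    truth: SyntheticTruth,
    n_rivers: int = 16,
    n_forests: int = 24,
    n_protected: int = 6,
):
    """Branching rivers with Strahler order/CSI/URB, forest points with
    log-uniform areas in [1, 10000] ha, and protected polygons covering all
    protection kinds.

    Strahler orders cycle through 1..8 so both sides of the ``order > 4``
    river-selection filter are always exercised.
    """
    xmin, ymin, xmax, ymax = extent
    rng = np.random.default_rng([truth.seed, 4])
    span = min(xmax - xmin, ymax - ymin)

    rivers: list[RiverSegment] = []
    for k in range(n_rivers):
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        heading = rng.uniform(0, 2 * np.pi)
        pts = [(x, y)]
        for _ in range(rng.integers(4, 10)):
            heading += rng.normal(0, 0.5)
            step = span * 0.03
            x = float(np.clip(x + step * np.cos(heading), xmin, xmax))
            y = float(np.clip(y + step * np.sin(heading), ymin, ymax))
            pts.append((x, y))
        rivers.append(
            RiverSegment(
                coords=tuple(pts),
                strahler_order=int(k % 8 + 1),
                csi=float(rng.uniform(0, 100)),
                urb=float(rng.uniform(0, 100)),
            )
        )

    forests: list[ForestSite] = []
    for k in range(n_forests):
        forests.append(
            ForestSite(
                lon=float(rng.uniform(xmin, xmax)),
                lat=float(rng.uniform(ymin, ymax)),
                area_ha=float(10 ** rng.uniform(0, 4)),  # log-uniform 1..10000 ha
                category=FOREST_CATEGORIES[k % len(FOREST_CATEGORIES)],
            )
        )

    protected: list[ProtectedArea] = []
    for k in range(max(n_protected, len(PROTECTED_KINDS))):
        cx = rng.uniform(xmin, xmax)
        cy = rng.uniform(ymin, ymax)
        w = rng.uniform(0.05, 0.2) * (xmax - xmin)
        h = rng.uniform(0.05, 0.2) * (ymax - ymin)
        poly = Polygon(
            [(cx - w / 2, cy - h / 2), (cx + w / 2, cy - h / 2), (cx + w / 2, cy + h / 2), (cx - w / 2, cy + h / 2)]
        )
        protected.append(ProtectedArea(polygon=poly, kind=PROTECTED_KINDS[k % len(PROTECTED_KINDS)]))

    return rivers, forests, protected


# --------------------------------------------------------------- full bundle
@dataclass
class LandscapeBundle:
    """Everything the pipeline consumes, on one shared grid."""

    truth: SyntheticTruth
    current_stack: list[RasterGrid]
    future_stacks: dict[tuple[str, int, str], list[RasterGrid]]
    dem: RasterGrid
    rivers: list[RiverSegment]
    forests: list[ForestSite]
    protected: list[ProtectedArea]
    occurrences: OccurrenceSet
    predictor_names: list[str]


def generate_landscape(
    seed: int,
    extent: tuple[float, float, float, float] = (-10.0, 35.0, 30.0, 55.0),
    resolution: float = 0.5,
    n_predictors: int = 6,
    n_occurrences: int = 260,
    truth: Optional[SyntheticTruth] = None,
    dem_factor: int = 2,
) -> LandscapeBundle:
    """One-call synthetic study system.

    Defaults mirror the study design at desk scale: a western-Palearctic-like
    lon/lat window, six predictors with one collinear pair, 260 presence
    records, three GCMs under two SSPs and three horizons. The DEM is
    generated ``dem_factor`` times finer than the predictors (elevations
    0–2500 m) on the same extent.
    """
    truth = truth or default_truth(seed, n_predictors)
    current, future = generate_environment(extent, resolution, n_predictors, truth)
    occ = sample_true_occurrences(current, truth, n_occurrences, seed=seed)

    nrows, ncols = current[0].values.shape
    rng = np.random.default_rng([seed, 5])
    dem_field = gaussian_filter(
        rng.standard_normal((nrows * dem_factor, ncols * dem_factor)),
        sigma=truth.smooth_sigma * dem_factor,
        mode="reflect",
    )
    dem_field = (dem_field - dem_field.min()) / (np.ptp(dem_field) + 1e-12) * 2500.0
    fine_mask = np.repeat(np.repeat(current[0].mask, dem_factor, axis=0), dem_factor, axis=1)
    dem = RasterGrid(
        np.where(fine_mask, dem_field, np.nan), extent[0], extent[1], resolution / dem_factor
    )
    rivers, forests, protected = generate_rivers_forests_protected(extent, truth)
    names = [f"P{i}" for i in range(n_predictors)]
    return LandscapeBundle(
        truth=truth,
        current_stack=current,
        future_stacks=future,
        dem=dem,
        rivers=rivers,
        forests=forests,
        protected=protected,
        occurrences=occ,
        predictor_names=names,
    )


# ------------------------------------------------------------------- GeoJSON
def rivers_to_geojson(rivers: Sequence[RiverSegment], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": [list(c) for c in r.coords]},
            "properties": {"strahler_order": r.strahler_order, "CSI": r.csi, "URB": r.urb},
        }
        for r in rivers
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def forests_to_geojson(forests: Sequence[ForestSite], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [f.lon, f.lat]},
            "properties": {"area_ha": f.area_ha, "category": f.category},
        }
        for f in forests
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def protected_to_geojson(protected: Sequence[ProtectedArea], path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(p.polygon), "properties": {"kind": p.kind}}
        for p in protected
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
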