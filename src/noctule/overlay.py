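"""Couple-and-weigh post-modelling: elevation preference, river
connectivity-functionality, forest point-to-polygon conversion, and the
weighted overlay that merges the three 1-to-10 layers into the weighted
suitability map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .geo import geodesic_circle, round_half_up
from .grids import RasterGrid, aggregate
from .occurrences import OccurrenceSet
from .synth import ForestSite, RiverSegment

__all__ = [
    "ElevationPreference",
    "ForestPolygon",
    "elevation_preference_curve",
    "reclassify_dem",
    "river_functionality_index",
    "forest_point_to_polygon",
    "forest_radius_m",
    "weighted_overlay",
]


@dataclass
class ElevationPreference:
    """Occurrence-frequency preference per 100-m elevation band, on 1-10."""

    bin_edges: np.ndarray  # len = n_bins + 1, meters
    bin_values: np.ndarray  # integers 1..10 per bin

    def value_at(self, elevation):
        """Preference class for elevations; bands outside the occupied range
        score the minimum class 1."""
        e = np.asarray(elevation, dtype=float)
        idx = np.searchsorted(self.bin_edges, e, side="right") - 1
        out = np.ones(e.shape, dtype=float)
        inside = (idx >= 0) & (idx < len(self.bin_values)) & np.isfinite(e)
        out[inside] = self.bin_values[idx[inside]]
        out[~np.isfinite(e)] = np.nan
        return out


def elevation_preference_curve(
    occ: OccurrenceSet, dem: RasterGrid, bin_width_m: float = 100.0
) -> ElevationPreference:
    """Normalize occurrence counts along the elevation gradient to 1-10.

    Elevations at occurrences are binned into ``bin_width_m``-wide bands
    aligned to multiples of the width; each band's count is min-max rescaled
    to 1..10 with half-up rounding. If every band in the occupied range has
    the same count, occupied bands all score 10.
    """
    if len(occ) == 0:
        raise ValueError("no occurrences for the elevation preference curve")
    elev = dem.value_at(occ.lons, occ.lats)
    elev = elev[np.isfinite(elev)]
    if elev.size == 0:
        raise ValueError("all occurrences fall on nodata DEM cells")
    lo = np.floor(elev.min() / bin_width_m) * bin_width_m
    hi = np.floor(elev.max() / bin_width_m) * bin_width_m + bin_width_m
    edges = np.arange(lo, hi + bin_width_m / 2, bin_width_m)
    counts, _ = np.histogram(elev, bins=edges)
    cmin, cmax = counts.min(), counts.max()
    if cmax == cmin:
        values = np.full(len(counts), 10, dtype=int)
    else:
        values = 1 + round_half_up(9.0 * (counts - cmin) / (cmax - cmin))
    return ElevationPreference(bin_edges=edges, bin_values=values)


def reclassify_dem(dem: RasterGrid, pref: ElevationPreference) -> RasterGrid:
    """DEM raster mapped through the elevation preference curve (1-10)."""
    return dem.like(pref.value_at(dem.values))


def river_functionality_index(
    rivers: Sequence[RiverSegment],
    template: RasterGrid,
    order_threshold: int = 4,
) -> RasterGrid:
    """Rasterized connectivity-functionality index of the major rivers, 1-10.

    Only reaches with Strahler order strictly above ``order_threshold`` are
    kept (the major riverine areas a large bat uses to roost, forage and
    move). The raw index CSI - URB is min-max rescaled over the retained
    reaches to 1..10 (half-up rounding); each raster cell takes the maximum
    class of the reaches crossing it, and riverless cells score 1.
    """
    kept = [r for r in rivers if r.strahler_order > order_threshold]
    out = np.full(template.values.shape, 1.0)
    out[~template.mask] = np.nan
    if not kept:
        warnings.warn("no river reaches above the Strahler-order threshold; all-1 raster")
        return template.like(out)
    raw = np.array([r.csi - r.urb for r in kept])
    rmin, rmax = raw.min(), raw.max()
    if rmax == rmin:
        classes = np.full(len(kept), 10, dtype=int)
    else:
        classes = 1 + round_half_up(9.0 * (raw - rmin) / (rmax - rmin))
    step = template.res / 3.0
    for seg, cls in zip(kept, classes):
        pts = _densify(np.asarray(seg.coords, dtype=float), step)
        rows, cols = template.index_of(pts[:, 0], pts[:, 1])
        ok = (rows >= 0) & (rows < template.nrows) & (cols >= 0) & (cols < template.ncols)
        for r_, c_ in zip(rows[ok], cols[ok]):
            if np.isfinite(out[r_, c_]):
                out[r_, c_] = max(out[r_, c_], float(cls))
    return template.like(out)


def _densify(coords: np.ndarray, step: float) -> np.ndarray:
    pts = [coords[0]]
    for a, b in zip(coords[:-1], coords[1:]):
        seg_len = float(np.hypot(*(b - a)))
        n = max(int(np.ceil(seg_len / step)), 1)
        for t in np.linspace(0, 1, n + 1)[1:]:
            pts.append(a + t * (b - a))
    return np.asarray(pts)


# ------------------------------------------------------------------ forests
@dataclass
class ForestPolygon:
    """An old-growth forest as an area-equivalent disk refined by a forest
    mask (the disk minus non-forest cells)."""

    center: tuple[float, float]
    radius_m: float
    polygon: Polygon
    area_ha: float
    category: str


def forest_radius_m(area_ha: float) -> float:
    """Radius (m) of the disk whose area equals the reported forest area:
    r = sqrt(area_ha * 10000 / pi)."""
    if area_ha <= 0:
        raise ValueError("forest area must be positive")
    return float(np.sqrt(area_ha * 10000.0 / np.pi))


def forest_point_to_polygon(
    forest: ForestSite, forest_mask: Optional[RasterGrid] = None
) -> ForestPolygon:
    """Convert a forest point with reported area into a refined polygon.

    A geodesic buffer of the area-equivalent radius is drawn around the
    point; if a boolean forest mask raster is given, cells where the mask is
    false (or nodata) are cut out of the buffer.
    """
    radius = forest_radius_m(forest.area_ha)
    ring = geodesic_circle(forest.lon, forest.lat, radius)
    poly = Polygon(ring)
    if forest_mask is not None:
        minx, miny, maxx, maxy = poly.bounds
        r0, c0 = forest_mask.index_of(minx, maxy)
        r1, c1 = forest_mask.index_of(maxx, miny)
        boxes = []
        for r_ in range(max(r0, 0), min(r1 + 1, forest_mask.nrows)):
            for c_ in range(max(c0, 0), min(c1 + 1, forest_mask.ncols)):
                v = forest_mask.values[r_, c_]
                if not (np.isfinite(v) and v > 0):
                    x0 = forest_mask.xmin + c_ * forest_mask.res
                    y1 = forest_mask.ymax - r_ * forest_mask.res
                    boxes.append(box(x0, y1 - forest_mask.res, x0 + forest_mask.res, y1))
        if boxes:
            poly = poly.difference(unary_union(boxes))
    lat = forest.lat
    deg_km = 2 * np.pi * 6371.0088 / 360.0
    area_ha = poly.area * (deg_km**2) * np.cos(np.radians(lat)) * 100.0
    return ForestPolygon(
        center=(forest.lon, forest.lat),
        radius_m=radius,
        polygon=poly,
        area_ha=float(area_ha),
        category=forest.category,
    )


# ----------------------------------------------------------- weighted overlay
def weighted_overlay(
    climate: RasterGrid,
    elevation: RasterGrid,
    rivers: RasterGrid,
    weights: tuple[float, float, float] = (0.5, 0.25, 0.25),
) -> RasterGrid:
    """Cell-wise weighted combination of the three 1-to-10 layers.

    The elevation and river layers may come at a finer resolution; they are
    upscaled to the climate grid by block aggregation (mean for elevation
    classes, max for river classes, so narrow corridors survive). Weights
    must be non-negative and sum to 1; the result is rounded half-up to an
    integer 1-10 and nodata in the climate layer propagates.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be non-negative and sum to 1")
    elevation = _match_resolution(elevation, climate, how="mean")
    rivers = _match_resolution(rivers, climate, how="max")
    vals = (
        w[0] * climate.values
        + w[1] * np.where(np.isfinite(elevation.values), elevation.values, 1.0)
        + w[2] * np.where(np.isfinite(rivers.values), rivers.values, 1.0)
    )
    out = np.clip(round_half_up(np.where(np.isfinite(vals), vals, 0.0)).astype(float), 1, 10)
    out[~climate.mask] = np.nan
    return climate.like(out)


def _match_resolution(layer: RasterGrid, template: RasterGrid, how: str) -> RasterGrid:
    if layer.values.shape == template.values.shape:
        return layer
    factor = layer.nrows // template.nrows
    if factor * template.nrows != layer.nrows or factor * template.ncols != layer.ncols:
        raise ValueError("layer resolution must be an integer multiple of the template's")
    return aggregate(layer, factor, how=how)
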