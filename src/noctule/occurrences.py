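"""Occurrence records: filtering, pairwise distance statistics, longitude groups.

Presence records for a wide-ranging species come from heterogeneous sources
(literature, GBIF). Before model fitting they are screened for age, for
coordinate precision compatible with the working raster resolution, and for
duplicates within a raster cell.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .geo import haversine_km, pairwise_haversine_km

__all__ = [
    "OccurrenceRecord",
    "OccurrenceSet",
    "filter_records",
    "pairwise_distance_stats",
    "assign_longitude_groups",
    "read_occurrence_csv",
    "write_occurrence_csv",
]

#: Default longitude breaks delimiting the West / Central / East groups (°E).
DEFAULT_LONGITUDE_BREAKS = (-15.0, 0.0, 15.0, 50.0)
DEFAULT_GROUP_NAMES = ("West", "Central", "East")


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single presence record (WGS84 decimal degrees)."""

    lon: float
    lat: float
    year: Optional[int] = None
    source: str = "gbif"
    coord_decimals: Optional[int] = None
    group: Optional[str] = None

    def __post_init__(self):
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"coordinates out of range: ({self.lon}, {self.lat})")

    def decimals(self) -> int:
        """Coordinate precision in decimal places.

        Falls back to the printed decimals of lon/lat when no explicit
        precision metadata is carried.
        """
        if self.coord_decimals is not None:
            return self.coord_decimals
        return max(_printed_decimals(self.lon), _printed_decimals(self.lat))


def _printed_decimals(x: float) -> int:
    s = repr(float(x))
    if "e" in s or "E" in s:
        return 15
    if "." not in s:
        return 0
    return len(s.split(".")[1].rstrip("0"))


@dataclass
class OccurrenceSet:
    """A filtered collection of presence records with provenance counters."""

    records: list[OccurrenceRecord] = field(default_factory=list)
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lons(self) -> np.ndarray:
        return np.array([r.lon for r in self.records], dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return np.array([r.lat for r in self.records], dtype=float)

    @property
    def groups(self) -> list[Optional[str]]:
        return [r.group for r in self.records]


def filter_records(
    raw: Iterable[OccurrenceRecord],
    min_year: int = 1970,
    max_coord_error_arcmin: float = 2.5,
    cell_size: float = 2.5 / 60.0,
) -> OccurrenceSet:
    """Screen raw records for age, positional precision, and cell duplicates.

    Rules, applied in order, with per-rule drop counts reported:

    1. *year*: drop records older than ``min_year`` (records with no year are
       kept — the year rule only rejects positively dated old records);
    2. *precision*: the positional uncertainty implied by the printed decimal
       places, ``0.5 * 10**-decimals`` degrees, must not exceed
       ``max_coord_error_arcmin`` (in arc-minutes);
    3. *duplicate*: one record per raster cell of size ``cell_size`` degrees.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    counts = {"year": 0, "precision": 0, "duplicate": 0}
    max_err_deg = max_coord_error_arcmin / 60.0
    kept: list[OccurrenceRecord] = []
    seen_cells: set[tuple[int, int]] = set()
    for rec in raw:
        if rec.year is not None and rec.year < min_year:
            counts["year"] += 1
            continue
        if 0.5 * 10.0 ** (-rec.decimals()) > max_err_deg:
            counts["precision"] += 1
            continue
        cell = (int(np.floor(rec.lon / cell_size)), int(np.floor(rec.lat / cell_size)))
        if cell in seen_cells:
            counts["duplicate"] += 1
            continue
        seen_cells.add(cell)
        kept.append(rec)
    return OccurrenceSet(records=kept, drop_counts=counts)


def pairwise_distance_stats(occ: OccurrenceSet, planar: bool = False) -> dict:
    """Mean and median distance (km) over all unordered record pairs.

    Distances are great-circle by default (spherical earth, R = 6371.0088 km);
    ``planar=True`` instead treats degrees as planar coordinates scaled by the
    meridional arc (111.195 km/deg), for comparison with projected workflows.
    """
    n = len(occ)
    if n < 2:
        raise ValueError("need at least 2 records for pairwise distances")
    if planar:
        deg_km = 2 * np.pi * 6371.0088 / 360.0
        xy = np.column_stack([occ.lons, occ.lats]) * deg_km
        from scipy.spatial.distance import pdist

        d = pdist(xy)
    else:
        full = pairwise_haversine_km(occ.lons, occ.lats)
        iu = np.triu_indices(n, k=1)
        d = full[iu]
    return {"mean_km": float(np.mean(d)), "median_km": float(np.median(d)), "n_pairs": int(d.size)}


def assign_longitude_groups(
    occ: OccurrenceSet,
    breaks: Sequence[float] = DEFAULT_LONGITUDE_BREAKS,
    names: Sequence[str] = DEFAULT_GROUP_NAMES,
) -> OccurrenceSet:
    """Label records by longitude band, half-open on the left edge.

    With the default breaks (-15, 0, 15, 50), a record at 0.0°E falls in the
    Central band and one at 15.0°E in the East band. Records outside the
    overall range are labelled ``"outside"`` and counted in
    ``drop_counts["outside_group"]``; downstream overlap analyses ignore them.
    """
    breaks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    if len(names) != len(breaks) - 1:
        raise ValueError("need one name per interval")
    out: list[OccurrenceRecord] = []
    outside = 0
    for rec in occ.records:
        label = "outside"
        for lo, hi, name in zip(breaks, breaks[1:], names):
            if lo <= rec.lon < hi:
                label = name
                break
        if rec.lon == breaks[-1]:  # closed top edge on the last band
            label = names[-1]
        if label == "outside":
            outside += 1
        out.append(replace(rec, group=label))
    counts = dict(occ.drop_counts)
    counts["outside_group"] = outside
    return OccurrenceSet(records=out, drop_counts=counts)


# ------------------------------------------------------------------------ I/O
def write_occurrence_csv(occ: OccurrenceSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lon", "lat", "year", "source", "group"])
        for r in occ.records:
            writer.writerow([r.lon, r.lat, r.year if r.year is not None else "", r.source, r.group or ""])


def read_occurrence_csv(path) -> OccurrenceSet:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                OccurrenceRecord(
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    year=int(row["year"]) if row.get("year") else None,
                    source=row.get("source", "gbif") or "gbif",
                    group=row.get("group") or None,
                )
            )
    return OccurrenceSet(records=records)
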