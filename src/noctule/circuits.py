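"""Circuit-theory landscape connectivity.

The weighted suitability raster becomes an electrical network: every valid
cell is a node whose conductance equals its suitability class, neighboring
cells are joined by resistors, and movement corridors show up as cells
carrying high current between focal populations (pairwise mode) or from
populations toward destination areas such as old-growth forests (advanced
mode). Effective resistance between two focal nodes measures their
isolation; the standardized connectivity change index (SCCI) compares
current maps between scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import LinearOperator, cg
from shapely.geometry import Point
from shapely.prepared import prep

from .geo import cross_haversine_km
from .grids import RasterGrid
from .occurrences import OccurrenceSet
from .overlay import ForestPolygon

__all__ = [
    "ConductanceGrid",
    "PairwiseResult",
    "CurrentMap",
    "raster_to_graph",
    "solve_pairwise",
    "solve_advanced",
    "compute_scci",
    "classify_reachable_forests",
]

DENSE_NODE_LIMIT = 5000


@dataclass
class ConductanceGrid:
    """Raster-as-circuit: node indexing, edge list, and cell conductances."""

    grid: RasterGrid
    neighborhood: str  # "four" | "eight"
    node_index: np.ndarray  # (nrows, ncols) int, -1 on nodata
    edges: np.ndarray  # (n_edges, 2) node ids
    conductances: np.ndarray  # (n_edges,)

    @property
    def n_nodes(self) -> int:
        return int(self.node_index.max()) + 1

    def node_of(self, lon: float, lat: float) -> int:
        """Graph node of the cell containing a point; -1 if nodata/outside."""
        if not self.grid.contains(lon, lat):
            return -1
        r, c = self.grid.index_of(lon, lat)
        return int(self.node_index[r, c])

    def laplacian(self) -> sp.csr_matrix:
        n = self.n_nodes
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.conductances
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([-w, -w, w, w])
        return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def raster_to_graph(ws: RasterGrid, neighborhood: str = "eight", invert: bool = False) -> ConductanceGrid:
    """Build the circuit graph from a 1-to-10 weighted suitability raster.

    Cell conductance is the suitability value itself (``invert=True``
    instead uses the resistance transform R = 11 - ws, i.e. conductance
    1/(11 - ws), for sensitivity runs). Edge conductance is the mean of the
    two cell conductances; diagonal edges (eight-neighborhood) are divided
    by sqrt(2) to account for the longer hop.
    """
    if neighborhood not in ("four", "eight"):
        raise ValueError("neighborhood must be 'four' or 'eight'")
    valid = ws.mask
    if not valid.any():
        raise ValueError("all-nodata raster")
    vals = ws.values
    if np.nanmin(vals) < 0:
        raise ValueError("conductances must be non-negative")
    cond = 1.0 / (11.0 - vals) if invert else vals

    node_index = np.full(vals.shape, -1, dtype=int)
    node_index[valid] = np.arange(valid.sum())

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == "eight":
        offsets += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    edges, weights = [], []
    nr, nc = vals.shape
    for dr, dc, length in offsets:
        r0, r1 = slice(0, nr - dr), slice(dr, nr)
        if dc >= 0:
            c0, c1 = slice(0, nc - dc), slice(dc, nc)
        else:
            c0, c1 = slice(-dc, nc), slice(0, nc + dc)
        a, b = node_index[r0, c0], node_index[r1, c1]
        ca, cb = cond[r0, c0], cond[r1, c1]
        ok = (a >= 0) & (b >= 0)
        edges.append(np.column_stack([a[ok], b[ok]]))
        weights.append((ca[ok] + cb[ok]) / 2.0 / length)
    edges = np.vstack(edges)
    weights = np.concatenate(weights)
    return ConductanceGrid(
        grid=ws.like(np.where(valid, cond, np.nan)),
        neighborhood=neighborhood,
        node_index=node_index,
        edges=edges,
        conductances=weights,
    )


# ------------------------------------------------------------------- solvers
class _GroundedSolver:
    """Solve L v = b with a set of grounded (zero-potential) nodes removed.

    Dense Cholesky below :data:`DENSE_NODE_LIMIT` unknowns, otherwise
    conjugate gradient with diagonal (Jacobi) preconditioning.
    """

    def __init__(self, L: sp.csr_matrix, free: np.ndarray):
        self.free = free
        self.sub = L[np.ix_(free, free)] if isinstance(L, np.ndarray) else L[free][:, free]
        self.n = len(free)
        if self.n < DENSE_NODE_LIMIT:
            self._cho = scipy.linalg.cho_factor(self.sub.toarray())
            self._mode = "dense"
        else:
            d = self.sub.diagonal()
            d[d == 0] = 1.0
            self._M = LinearOperator((self.n, self.n), matvec=lambda x: x / d)
            self._mode = "cg"

    def solve(self, b_free: np.ndarray) -> np.ndarray:
        if self._mode == "dense":
            return scipy.linalg.cho_solve(self._cho, b_free)
        x, info = cg(self.sub, b_free, M=self._M, rtol=1e-10, atol=0.0, maxiter=20 * self.n)
        if info != 0:
            raise RuntimeError(f"conjugate gradient failed to converge (info={info})")
        return x


def _cell_current_map(g: ConductanceGrid, potentials: np.ndarray) -> np.ndarray:
    """Per-cell current magnitude: half the sum of absolute incident edge
    currents (so a through-cell on a series path carries its through
    current once)."""
    i, j = g.edges[:, 0], g.edges[:, 1]
    edge_cur = np.abs(g.conductances * (potentials[i] - potentials[j]))
    node_cur = np.zeros(g.n_nodes)
    np.add.at(node_cur, i, edge_cur)
    np.add.at(node_cur, j, edge_cur)
    node_cur /= 2.0
    out = np.full(g.grid.values.shape, np.nan)
    out[g.node_index >= 0] = node_cur[g.node_index[g.node_index >= 0]]
    return out


@dataclass
class PairwiseResult:
    """All-pairs effective resistances plus the summed current map."""

    resistances: np.ndarray  # (n_focal, n_focal), inf across components
    cumulative_current: RasterGrid
    focal_nodes: list[int]


def solve_pairwise(g: ConductanceGrid, focal: Sequence[tuple[float, float]]) -> PairwiseResult:
    """Effective resistance and current between every unordered focal pair.

    For each pair, a unit current enters one node and leaves the other; the
    potential drop between them is the effective resistance and the per-cell
    absolute currents are accumulated over pairs. Pairs in different graph
    components get infinite resistance and contribute no current.
    """
    nodes = []
    for lon, lat in focal:
        node = g.node_of(lon, lat)
        if node < 0:
            raise ValueError(f"focal point ({lon}, {lat}) does not fall on a valid cell")
        nodes.append(node)
    uniq = []
    for n_ in nodes:
        if n_ in uniq:
            warnings.warn("coincident focal cells merged")
        else:
            uniq.append(n_)
    nodes = uniq
    if len(nodes) < 2:
        raise ValueError("need at least 2 distinct focal cells")

    L = g.laplacian()
    n_comp, comp = connected_components(L != 0, directed=False)
    resist = np.zeros((len(nodes), len(nodes)))
    cum = np.zeros(g.grid.values.shape)
    solvers: dict[int, tuple[_GroundedSolver, np.ndarray]] = {}

    def solver_for(component: int):
        if component not in solvers:
            members = np.nonzero(comp == component)[0]
            free = members[:-1]  # ground the last node of the component
            inv = -np.ones(g.n_nodes, dtype=int)
            inv[free] = np.arange(len(free))
            solvers[component] = (_GroundedSolver(L, free), inv)
        return solvers[component]

    disconnected = 0
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            s, t = nodes[a], nodes[b]
            if comp[s] != comp[t]:
                resist[a, b] = resist[b, a] = np.inf
                disconnected += 1
                continue
            solver, inv = solver_for(comp[s])
            rhs = np.zeros(solver.n)
            if inv[s] >= 0:
                rhs[inv[s]] += 1.0
            if inv[t] >= 0:
                rhs[inv[t]] -= 1.0
            v_free = solver.solve(rhs)
            v = np.zeros(g.n_nodes)
            v[solver.free] = v_free
            vs = v[s]
            vt = v[t]
            resist[a, b] = resist[b, a] = vs - vt
            cur = _cell_current_map(g, v)
            cum += np.where(np.isfinite(cur), cur, 0.0)
    if disconnected:
        warnings.warn(f"{disconnected} focal pair(s) in disconnected components: resistance inf")
    cum_grid = g.grid.like(np.where(g.grid.mask, cum, np.nan))
    return PairwiseResult(resistances=resist, cumulative_current=cum_grid, focal_nodes=nodes)


@dataclass
class CurrentMap:
    """Per-cell current magnitude for one scenario/solve."""

    grid: RasterGrid
    mode: str  # "pairwise" | "advanced"
    sources: list[int]
    grounds: list[int]


def solve_advanced(
    g: ConductanceGrid,
    sources: Sequence[tuple[tuple[float, float], float]],
    grounds: Sequence,
) -> CurrentMap:
    """One multi-source solve: current injected at source cells flows to
    zero-potential ground areas (e.g. old-growth forest polygons).

    ``sources`` is a list of ((lon, lat), amps); ``grounds`` a list of
    shapely polygons whose interior cells are tied to zero potential
    (infinite-conductance ground). Sources falling inside a ground are
    ignored with a warning; nodes with no path to any ground carry zero
    current.
    """
    lons2d, lats2d = g.grid.center_grids()
    ground_mask = np.zeros(g.grid.values.shape, dtype=bool)
    for poly in grounds:
        pp = prep(poly)
        minx, miny, maxx, maxy = poly.bounds
        cand = (
            (lons2d >= minx) & (lons2d <= maxx) & (lats2d >= miny) & (lats2d <= maxy) & g.grid.mask
        )
        hit = False
        for r_, c_ in zip(*np.nonzero(cand)):
            if pp.intersects(Point(lons2d[r_, c_], lats2d[r_, c_])):
                ground_mask[r_, c_] = True
                hit = True
        if not hit:
            # sub-cell ground area: snap to the cell containing its centroid
            cx, cy = poly.centroid.x, poly.centroid.y
            if g.grid.contains(cx, cy):
                r_, c_ = g.grid.index_of(cx, cy)
                if g.node_index[r_, c_] >= 0:
                    ground_mask[r_, c_] = True
    ground_nodes = set(int(v) for v in g.node_index[ground_mask] if v >= 0)
    if not ground_nodes:
        raise ValueError("no valid ground cells")

    inj = np.zeros(g.n_nodes)
    src_nodes = []
    for (lon, lat), amps in sources:
        node = g.node_of(lon, lat)
        if node < 0:
            raise ValueError(f"source ({lon}, {lat}) does not fall on a valid cell")
        if node in ground_nodes:
            warnings.warn(f"source ({lon}, {lat}) lies inside a ground area; ignored")
            continue
        inj[node] += amps
        src_nodes.append(node)
    if not src_nodes:
        raise ValueError("no usable sources (all inside grounds?)")

    L = g.laplacian()
    n_comp, comp = connected_components(L != 0, directed=False)
    grounded_comps = {comp[n_] for n_ in ground_nodes}
    free = np.array(
        [
            n_
            for n_ in range(g.n_nodes)
            if n_ not in ground_nodes and comp[n_] in grounded_comps
        ],
        dtype=int,
    )
    v = np.zeros(g.n_nodes)
    if free.size:
        solver = _GroundedSolver(L, free)
        v[free] = solver.solve(inj[free])
    cur = _cell_current_map(g, v)
    return CurrentMap(
        grid=g.grid.like(np.where(g.grid.mask, np.where(np.isfinite(cur), cur, 0.0), np.nan)),
        mode="advanced",
        sources=src_nodes,
        grounds=sorted(ground_nodes),
    )


def compute_scci(current_now: CurrentMap, current_future: CurrentMap) -> RasterGrid:
    """Standardized Connectivity Change Index, cellwise (F - C)/(F + C).

    -1 is complete connectivity loss, +1 is gain from zero, 0 is stability;
    cells with no current in either scenario score 0.
    """
    c = current_now.grid.values
    f = current_future.grid.values
    if not current_now.grid.same_grid(current_future.grid, check_mask=False):
        raise ValueError("current maps must share a grid")
    if np.nanmin(c) < 0 or np.nanmin(f) < 0:
        raise ValueError("negative currents are a contract violation upstream")
    denom = f + c
    with np.errstate(invalid="ignore", divide="ignore"):
        scci = np.where(denom > 0, (f - c) / denom, 0.0)
    scci = np.where(np.isfinite(c) & np.isfinite(f), scci, np.nan)
    return current_now.grid.like(scci)


def classify_reachable_forests(
    forests: Sequence[ForestPolygon],
    occ: OccurrenceSet,
    radius_km: float = 130.0,
    densify_deg: float = 0.01,
) -> list[dict]:
    """Flag forests within ``radius_km`` (great-circle) of any occurrence.

    The default 130 km is the maximum daily foraging transit recorded for
    the species; the distance is the minimum from the forest polygon (zero
    for occurrences inside) to the occurrence points, with the polygon
    boundary densified for the vertex scan.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    out = []
    for f in forests:
        if f.polygon.is_empty or f.polygon.area == 0:
            coords = np.asarray([f.center])
        else:
            import shapely

            coords = shapely.get_coordinates(f.polygon.boundary.segmentize(densify_deg))
        d = cross_haversine_km(occ.lons, occ.lats, coords[:, 0], coords[:, 1]).min(axis=1)
        inside = np.array([f.polygon.covers(Point(x, y)) for x, y in zip(occ.lons, occ.lats)])
        d = np.where(inside, 0.0, d)
        dmin = float(d.min())
        out.append(
            {
                "category": f.category,
                "center": f.center,
                "min_distance_km": dmin,
                "status": "reachable" if dmin <= radius_km else "remote",
            }
        )
    return out
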