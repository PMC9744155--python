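import numpy as np
import pytest
from shapely.geometry import box

from noctule.circuits import (
    classify_reachable_forests,
    compute_scci,
    raster_to_graph,
    solve_advanced,
    solve_pairwise,
)
from noctule.geo import cross_haversine_km
from noctule.grids import RasterGrid
from noctule.occurrences import OccurrenceRecord, OccurrenceSet
from noctule.overlay import ForestPolygon


def _grid(values, res=1.0):
    return RasterGrid(np.asarray(values, dtype=float), 0.0, 0.0, res)


def _center(g, r, c):
    lons, lats = g.cell_centers()
    return (lons[c], lats[r])


def dense_resistance(cg, s, t):
    """Oracle: effective resistance from the dense Laplacian pseudo-inverse.

    ``hermitian=True`` keeps the SVD cutoff from discarding genuine small
    eigenvalues (only the one exact null vector must go).
    """
    L = cg.laplacian().toarray()
    Lp = np.linalg.pinv(L, hermitian=True)
    return Lp[s, s] + Lp[t, t] - 2 * Lp[s, t]


class TestGraphConstruction:
    def test_1x3_uniform_two_unit_edges(self):
        cg = raster_to_graph(_grid([[1.0, 1.0, 1.0]]), "four")
        assert len(cg.edges) == 2
        np.testing.assert_allclose(cg.conductances, 1.0)

    def test_edge_count_matches_adjacency_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 11, (6, 7)).astype(float)
        vals[rng.uniform(size=(6, 7)) < 0.2] = np.nan
        g = _grid(vals)
        for neigh, offsets in [
            ("four", [(0, 1), (1, 0)]),
            ("eight", [(0, 1), (1, 0), (1, 1), (1, -1)]),
        ]:
            cg = raster_to_graph(g, neigh)
            count = 0
            for r in range(6):
                for c in range(7):
                    if not np.isfinite(vals[r, c]):
                        continue
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < 6 and 0 <= cc < 7 and np.isfinite(vals[rr, cc]):
                            count += 1
            assert len(cg.edges) == count

    def test_diagonal_edge_conductance_rule(self):
        vals = np.array([[2.0, np.nan], [np.nan, 2.0]])
        cg = raster_to_graph(_grid(vals), "eight")
        assert len(cg.edges) == 1
        assert cg.conductances[0] == pytest.approx(2.0 / np.sqrt(2.0))

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError):
            raster_to_graph(_grid([[np.nan, np.nan]]))

    def test_resistance_transform_flag(self):
        cg = raster_to_graph(_grid([[10.0, 10.0]]), "four", invert=True)
        assert cg.conductances[0] == pytest.approx(1.0)  # R = 11 - 10 = 1


class TestPairwise:
    def test_series_resistance_1x3(self):
        g = _grid([[1.0, 1.0, 1.0]])
        cg = raster_to_graph(g, "four")
        res = solve_pairwise(cg, [_center(g, 0, 0), _center(g, 0, 2)])
        assert res.resistances[0, 1] == pytest.approx(2.0, abs=1e-10)

    def test_parallel_paths_unit_resistance(self):
        # 3x3 ring: two 2-edge unit-conductance paths between opposite corners
        vals = np.array([[1.0, 1.0, 1.0], [1.0, np.nan, 1.0], [1.0, 1.0, 1.0]])
        g = _grid(vals)
        cg = raster_to_graph(g, "four")
        res = solve_pairwise(cg, [_center(g, 0, 1), _center(g, 2, 1)])
        # each side path has 4 unit edges; two in parallel -> R = 2
        assert res.resistances[0, 1] == pytest.approx(2.0, abs=1e-10)

    def test_matches_dense_oracle_on_random_grids(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            nr, nc = rng.integers(3, 7, 2)
            vals = rng.integers(1, 11, (nr, nc)).astype(float)
            g = _grid(vals)
            neigh = "eight" if trial % 2 else "four"
            cg = raster_to_graph(g, neigh)
            cells = rng.choice(nr * nc, size=2, replace=False)
            focal = [_center(g, i // nc, i % nc) for i in cells]
            res = solve_pairwise(cg, focal)
            s, t = res.focal_nodes
            oracle = dense_resistance(cg, s, t)
            assert res.resistances[0, 1] == pytest.approx(oracle, abs=1e-8)

    def test_resistance_matrix_is_a_metric(self):
        rng = np.random.default_rng(7)
        vals = rng.integers(1, 11, (5, 5)).astype(float)
        g = _grid(vals)
        cg = raster_to_graph(g, "eight")
        focal = [_center(g, r, c) for r, c in [(0, 0), (2, 3), (4, 1), (4, 4)]]
        R = solve_pairwise(cg, focal).resistances
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        assert np.all(np.diag(R) == 0)
        n = len(focal)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert R[i, j] <= R[i, k] + R[k, j] + 1e-10

    def test_rayleigh_monotonicity(self):
        rng = np.random.default_rng(8)
        vals = rng.integers(1, 10, (4, 4)).astype(float)
        g = _grid(vals)
        focal = [_center(g, 0, 0), _center(g, 3, 3)]
        base = solve_pairwise(raster_to_graph(g, "eight"), focal).resistances[0, 1]
        for r, c in [(1, 1), (2, 3), (0, 2)]:
            bumped = vals.copy()
            bumped[r, c] += 3.0
            rb = solve_pairwise(raster_to_graph(_grid(bumped), "eight"), focal).resistances[0, 1]
            assert rb <= base + 1e-10

    def test_disconnected_pair_infinite_with_warning(self):
        vals = np.array([[1.0, np.nan, 1.0]])
        g = _grid(vals)
        cg = raster_to_graph(g, "four")
        with pytest.warns(UserWarning, match="disconnected"):
            res = solve_pairwise(cg, [_center(g, 0, 0), _center(g, 0, 2)])
        assert np.isinf(res.resistances[0, 1])
        assert np.nansum(res.cumulative_current.values) == 0

    def test_current_conservation_at_interior_nodes(self):
        rng = np.random.default_rng(9)
        vals = rng.integers(1, 11, (5, 5)).astype(float)
        g = _grid(vals)
        cg = raster_to_graph(g, "eight")
        focal = [_center(g, 0, 0), _center(g, 4, 4)]
        nodes = [cg.node_of(*f) for f in focal]
        L = cg.laplacian().toarray()
        sub = np.delete(np.delete(L, nodes[1], 0), nodes[1], 1)
        rhs = np.zeros(cg.n_nodes)
        rhs[nodes[0]] = 1.0
        rhs = np.delete(rhs, nodes[1])
        v = np.zeros(cg.n_nodes)
        v[np.arange(cg.n_nodes) != nodes[1]] = np.linalg.solve(sub, rhs)
        balance = L @ v
        for n_ in range(cg.n_nodes):
            if n_ not in nodes:
                assert abs(balance[n_]) < 1e-8

    def test_grid_refinement_changes_resistance_mildly(self):
        coarse = _grid(np.full((4, 6), 5.0))
        fine = _grid(np.full((8, 12), 5.0), res=0.5)
        f_c = [_center(coarse, 1, 0), _center(coarse, 1, 5)]
        r_c = solve_pairwise(raster_to_graph(coarse, "eight"), f_c).resistances[0, 1]
        f_f = [_center(fine, 3, 0), _center(fine, 3, 11)]
        r_f = solve_pairwise(raster_to_graph(fine, "eight"), f_f).resistances[0, 1]
        # doubling resolution halves cell size; per-square resistance stays put
        assert abs(r_f - r_c) / r_c < 0.30


class TestAdvanced:
    def test_single_source_single_ground_matches_pairwise(self):
        rng = np.random.default_rng(10)
        vals = rng.integers(1, 11, (4, 4)).astype(float)
        g = _grid(vals)
        cg = raster_to_graph(g, "eight")
        src = _center(g, 0, 0)
        gnd_cell = _center(g, 3, 3)
        pair = solve_pairwise(cg, [src, gnd_cell])
        gnd_poly = box(gnd_cell[0] - 0.4, gnd_cell[1] - 0.4, gnd_cell[0] + 0.4, gnd_cell[1] + 0.4)
        adv = solve_advanced(cg, [(src, 1.0)], [gnd_poly])
        np.testing.assert_allclose(
            adv.grid.values, pair.cumulative_current.values, atol=1e-8
        )

    def test_total_current_into_grounds_conserved(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(1, 11, (5, 5)).astype(float)
        g = _grid(vals)
        cg = raster_to_graph(g, "eight")
        gnd = box(3.6, 0.1, 4.4, 0.9)  # bottom-right corner cell
        adv = solve_advanced(cg, [(_center(g, 0, 0), 1.0), (_center(g, 0, 2), 1.0)], [gnd])
        # ground cell current = half the incident |I| = total inflow / 2
        gnd_val = adv.grid.values[4, 4]
        assert gnd_val == pytest.approx(1.0, abs=1e-8)  # 2.0 amps in / 2

    def test_superposition_on_linear_network(self):
        rng = np.random.default_rng(12)
        vals = rng.integers(1, 11, (4, 5)).astype(float)
        g = _grid(vals)
        cg = raster_to_graph(g, "four")
        gnd = box(3.6, 3.1, 4.4, 3.9)
        s1, s2 = _center(g, 3, 0), _center(g, 3, 2)
        both = solve_advanced(cg, [(s1, 1.0), (s2, 1.0)], [gnd])
        # potentials superpose; compare summed potentials via doubled injection
        double_s1 = solve_advanced(cg, [(s1, 2.0)], [gnd])
        single_s1 = solve_advanced(cg, [(s1, 1.0)], [gnd])
        np.testing.assert_allclose(double_s1.grid.values, 2 * single_s1.grid.values, atol=1e-9)
        assert np.nanmax(both.grid.values) <= np.nanmax(single_s1.grid.values) + np.nanmax(
            solve_advanced(cg, [(s2, 1.0)], [gnd]).grid.values
        ) + 1e-9

    def test_source_inside_ground_ignored_with_warning(self):
        g = _grid(np.ones((3, 3)))
        cg = raster_to_graph(g, "four")
        gnd = box(-0.1, -0.1, 3.1, 1.1)  # bottom row
        with pytest.warns(UserWarning, match="ignored"):
            adv = solve_advanced(
                cg, [(_center(g, 2, 0), 1.0), (_center(g, 0, 2), 1.0)], [gnd]
            )
        assert adv.sources == [cg.node_of(*_center(g, 0, 2))]


class TestScci:
    def _cm(self, values):
        from noctule.circuits import CurrentMap

        return CurrentMap(grid=_grid(values), mode="advanced", sources=[], grounds=[])

    def test_equal_maps_give_zero(self):
        c = self._cm([[0.5, 1.0], [0.0, 2.0]])
        out = compute_scci(c, self._cm([[0.5, 1.0], [0.0, 2.0]]))
        np.testing.assert_allclose(out.values, 0.0)

    def test_endpoints(self):
        c = self._cm([[0.0, 1.0]])
        f = self._cm([[1.0, 0.0]])
        out = compute_scci(c, f)
        assert out.values[0, 0] == 1.0 and out.values[0, 1] == -1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(13)
        a = self._cm(rng.uniform(0, 2, (4, 4)))
        b = self._cm(rng.uniform(0, 2, (4, 4)))
        ab = compute_scci(a, b).values
        ba = compute_scci(b, a).values
        np.testing.assert_allclose(ab, -ba, atol=1e-12)

    def test_negative_current_rejected(self):
        with pytest.raises(ValueError):
            compute_scci(self._cm([[-0.1]]), self._cm([[0.1]]))

    def test_bounded(self):
        rng = np.random.default_rng(14)
        out = compute_scci(
            self._cm(rng.uniform(0, 5, (6, 6))), self._cm(rng.uniform(0, 5, (6, 6)))
        ).values
        assert np.nanmin(out) >= -1.0 and np.nanmax(out) <= 1.0


class TestReachability:
    def _forest(self, lon, lat, radius_deg=0.05):
        from shapely.geometry import Point

        return ForestPolygon(
            center=(lon, lat),
            radius_m=5000.0,
            polygon=Point(lon, lat).buffer(radius_deg),
            area_ha=100.0,
            category="Old-Growth Forest",
        )

    def test_threshold_classification(self):
        occ = OccurrenceSet(records=[OccurrenceRecord(0.0, 45.0)])
        # polygon edges sit ~1.1 km inside of the stated center distances
        near = self._forest(0.0, 45.0 + 120.0 / 111.195, radius_deg=0.01)
        far = self._forest(0.0, 45.0 + 135.0 / 111.195, radius_deg=0.01)
        out = classify_reachable_forests([near, far], occ, radius_km=130.0)
        assert out[0]["status"] == "reachable"
        assert out[1]["status"] == "remote"

    def test_flags_match_brute_force_scan(self):
        rng = np.random.default_rng(15)
        occ = OccurrenceSet(
            records=[
                OccurrenceRecord(float(lo), float(la))
                for lo, la in zip(rng.uniform(0, 10, 8), rng.uniform(40, 48, 8))
            ]
        )
        forests = [
            self._forest(float(lo), float(la))
            for lo, la in zip(rng.uniform(0, 10, 6), rng.uniform(40, 48, 6))
        ]
        out = classify_reachable_forests(forests, occ, radius_km=130.0)
        for f, res in zip(forests, out):
            import shapely

            coords = shapely.get_coordinates(f.polygon.exterior.segmentize(0.005))
            brute = cross_haversine_km(
                occ.lons, occ.lats, coords[:, 0], coords[:, 1]
            ).min()
            assert (brute <= 130.0) == (res["status"] == "reachable")
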