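import numpy as np
import pandas as pd
import pytest

from noctule.enm import (
    TrainingTable,
    TuningGrid,
    assign_case_weights,
    cv_rmse_curve,
    eligible_pseudoabsence_cells,
    sample_disk_pseudoabsences,
    tune_and_fit,
    vif_select,
)
from noctule.geo import haversine_km
from noctule.grids import RasterGrid
from noctule.occurrences import OccurrenceRecord, OccurrenceSet


class TestVif:
    def test_independent_predictors_retained_with_unit_vif(self):
        rng = np.random.default_rng(0)
        tbl = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        retained, trace = vif_select(tbl)
        assert retained == ["a", "b"]
        final = trace[-1]["vifs"]
        assert final["a"] == pytest.approx(1.0, abs=0.05)

    def test_linear_combination_removed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        c = a + b + rng.normal(scale=1e-3, size=500)
        tbl = pd.DataFrame({"a": a, "b": b, "c": c})
        # brute-force oracle: the max VIF must exceed the threshold
        max_vif = max(
            1.0 / (1.0 - _ols_r2(tbl[col], tbl.drop(columns=col))) for col in tbl
        )
        assert max_vif > 10
        retained, trace = vif_select(tbl)
        assert len(retained) == 2
        assert trace[0]["vif"] > 10

    def test_vif_exactly_at_threshold_is_removed(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=4000)
        noise = rng.normal(size=4000)
        # build b with R^2 = 0.9 exactly against a => VIF = 10.0
        a_std = (a - a.mean()) / a.std()
        n_std = noise - noise.mean()
        n_std -= (n_std @ a_std) / (a_std @ a_std) * a_std
        n_std /= n_std.std()
        b = np.sqrt(0.9) * a_std + np.sqrt(0.1) * n_std
        tbl = pd.DataFrame({"a": a_std, "b": b})
        retained, trace = vif_select(tbl, threshold=10.0 - 1e-9)
        assert len(retained) == 1

    def test_perfect_collinearity_removed_first_with_infinite_vif(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=100)
        tbl = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=100)})
        retained, trace = vif_select(tbl)
        assert trace[0]["vif"] == np.inf
        assert "c" in retained


def _ols_r2(y, X):
    A = np.column_stack([np.ones(len(y)), X.to_numpy()])
    coef, *_ = np.linalg.lstsq(A, y.to_numpy(), rcond=None)
    resid = y.to_numpy() - A @ coef
    return 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)


class TestPseudoAbsences:
    def _domain(self):
        # 40x40 cells of 0.5 deg covering a 20-deg window
        return RasterGrid(np.zeros((40, 40)), 0.0, 30.0, 0.5)

    def _occ(self):
        return OccurrenceSet(records=[OccurrenceRecord(10.0, 40.0), OccurrenceRecord(12.0, 42.0)])

    def test_all_samples_within_annulus(self):
        domain, occ = self._domain(), self._occ()
        pa = sample_disk_pseudoabsences(occ, domain, n=100, seed=0)
        for lon, lat in zip(pa["lon"], pa["lat"]):
            nearest = min(haversine_km(lon, lat, r.lon, r.lat) for r in occ.records)
            assert 130.0 <= nearest <= 250.0

    def test_eligible_cells_match_brute_force_scan(self):
        domain, occ = self._domain(), self._occ()
        rows, cols = eligible_pseudoabsence_cells(occ, domain)
        got = set(zip(rows.tolist(), cols.tolist()))
        lons, lats = domain.cell_centers()
        expected = set()
        for r in range(domain.nrows):
            for c in range(domain.ncols):
                nearest = min(haversine_km(lons[c], lats[r], p.lon, p.lat) for p in occ.records)
                if 130.0 <= nearest <= 250.0:
                    expected.add((r, c))
        assert got == expected

    def test_close_candidate_never_sampled(self):
        # single presence; a cell ~100 km away must be excluded
        domain = RasterGrid(np.zeros((3, 3)), 0.0, 0.0, 1.0)
        occ = OccurrenceSet(records=[OccurrenceRecord(0.5, 2.5)])
        rows, cols = eligible_pseudoabsence_cells(occ, domain)
        lons, lats = domain.cell_centers()
        for r, c in zip(rows, cols):
            assert haversine_km(lons[c], lats[r], 0.5, 2.5) >= 130.0

    def test_shortfall_returns_all_eligible_without_replacement(self):
        domain, occ = self._domain(), self._occ()
        rows, _ = eligible_pseudoabsence_cells(occ, domain)
        with pytest.warns(UserWarning, match="eligible"):
            pa = sample_disk_pseudoabsences(occ, domain, n=10_000, seed=0)
        assert len(pa) == len(rows)
        assert not pa.duplicated(["row", "col"]).any()

    def test_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            sample_disk_pseudoabsences(self._occ(), self._domain(), r_min_km=250, r_max_km=130)


class TestCaseWeights:
    def _table(self, n_pres, n_abs):
        n = n_pres + n_abs
        X = pd.DataFrame({"p": np.zeros(n)})
        y = np.array([1] * n_pres + [0] * n_abs)
        return TrainingTable(X=X, y=y, weights=np.ones(n), lon=np.zeros(n), lat=np.zeros(n))

    def test_260_presences_5000_absences(self):
        t = assign_case_weights(self._table(260, 5000))
        assert t.weights[t.y == 1][0] == pytest.approx(5000 / 260)

    def test_equal_counts_all_unit(self):
        t = assign_case_weights(self._table(20, 20))
        assert np.all(t.weights == 1.0)

    def test_sides_balance(self):
        t = assign_case_weights(self._table(10, 40))
        assert t.weights[t.y == 1][0] == 4.0
        assert t.weights[t.y == 1].sum() == pytest.approx(t.weights[t.y == 0].sum())

    def test_no_presences_rejected(self):
        with pytest.raises(ValueError):
            assign_case_weights(self._table(0, 10))


def _logistic_table(seed, n=600, n_pred=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_pred))
    logit = 2.0 * X[:, 0] - 1.0 * X[:, 1]
    p = 1 / (1 + np.exp(-logit))
    y = (rng.uniform(size=n) < p).astype(int)
    return TrainingTable(
        X=pd.DataFrame(X, columns=[f"P{i}" for i in range(n_pred)]),
        y=y,
        weights=np.ones(n),
        lon=rng.uniform(0, 10, n),
        lat=rng.uniform(40, 50, n),
    )


class TestTuning:
    def test_single_combination_returned(self):
        table = _logistic_table(0)
        grid = TuningGrid(
            shrinkage=(0.1,), interaction_depth=(2,), min_obs_in_node=(10,),
            bag_fraction=(0.8,), n_trees_max=60, cv_folds=3,
        )
        fit = tune_and_fit(table, grid, seed=0)
        assert fit.best_params["shrinkage"] == 0.1
        assert fit.best_params["interaction_depth"] == 2
        assert 1 <= fit.best_params["n_trees"] <= 60

    def test_winner_beats_every_other_combination_on_independent_reevaluation(self):
        table = _logistic_table(1)
        grid = TuningGrid(
            shrinkage=(0.05, 0.3), interaction_depth=(1, 3), min_obs_in_node=(10,),
            bag_fraction=(0.8,), n_trees_max=80, cv_folds=3,
        )
        fit = tune_and_fit(table, grid, seed=1)
        # independent exhaustive re-evaluation of the full grid
        best_rmse = {}
        for params in grid.combinations():
            curve = cv_rmse_curve(table, params, grid.n_trees_max, grid.cv_folds, seed=1)
            best_rmse[params] = curve.min()
        assert fit.rmse == pytest.approx(min(best_rmse.values()))

    def test_non_finite_predictors_rejected(self):
        table = _logistic_table(2)
        table.X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            TrainingTable(X=table.X, y=table.y, weights=table.weights, lon=table.lon, lat=table.lat)

    def test_reweighted_duplicate_absences_keep_ranking(self):
        """Doubling pseudo-absences with reweighting preserves the CV ranking."""
        table = _logistic_table(3, n=300)
        dup = TrainingTable(
            X=pd.concat([table.X, table.X[table.y == 0]], ignore_index=True),
            y=np.concatenate([table.y, np.zeros((table.y == 0).sum(), dtype=int)]),
            weights=np.ones(len(table.y) + (table.y == 0).sum()),
            lon=np.concatenate([table.lon, table.lon[table.y == 0]]),
            lat=np.concatenate([table.lat, table.lat[table.y == 0]]),
        )
        table = assign_case_weights(table)
        dup = assign_case_weights(dup)
        grid = TuningGrid(
            shrinkage=(0.05, 0.3), interaction_depth=(1,), min_obs_in_node=(10,),
            bag_fraction=(1.0,), n_trees_max=50, cv_folds=3,
        )
        fit_a = tune_and_fit(table, grid, seed=3)
        fit_b = tune_and_fit(dup, grid, seed=3)
        rank_a = fit_a.cv_table.sort_values("cv_rmse")["shrinkage"].tolist()
        rank_b = fit_b.cv_table.sort_values("cv_rmse")["shrinkage"].tolist()
        assert rank_a == rank_b
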