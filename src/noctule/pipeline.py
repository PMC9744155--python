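"""End-to-end study pipeline on a synthetic landscape.

Chains every stage of the analysis — landscape generation, occurrence
filtering, collinearity screen, disk pseudo-absences, boosted-tree tuning,
evaluation, current/future projection with MESS-weighted GCM combination,
the couple-and-weigh overlay, circuit connectivity with change indices, and
the niche-overlap / gap analyses — at a problem size a single CPU handles
in minutes. Each stage is a thin call into the corresponding module, so the
numbered analysis drivers and the tests exercise the same code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import circuits, enm, evaluation, overlap, overlay, projection, synth
from .occurrences import assign_longitude_groups, filter_records, pairwise_distance_stats

__all__ = ["StudyConfig", "StudyResult", "run_study"]


@dataclass
class StudyConfig:
    """Desk-scale study conditions.

    The spatial window, predictor count, occurrence count, GCM/SSP/horizon
    design, pseudo-absence annulus (130–250 km) and 130-km forest buffer
    mirror the full study; raster resolution, pseudo-absence count, tuning
    grid and focal-pair count are scaled down so the whole pipeline runs on
    one CPU in minutes.
    """

    extent: tuple[float, float, float, float] = (-10.0, 35.0, 30.0, 55.0)
    resolution: float = 0.5
    n_predictors: int = 6
    n_occurrences: int = 260
    n_pseudoabsences: int = 1000
    r_min_km: float = 130.0
    r_max_km: float = 250.0
    vif_threshold: float = 10.0
    tuning: enm.TuningGrid = field(
        default_factory=lambda: enm.TuningGrid(
            shrinkage=(0.05, 0.1),
            interaction_depth=(2, 3),
            min_obs_in_node=(10,),
            bag_fraction=(0.8,),
            n_trees_max=250,
            cv_folds=5,
        )
    )
    overlay_weights: tuple[float, float, float] = (0.5, 0.25, 0.25)
    n_focal_pairwise: int = 12
    forest_buffer_km: float = 130.0
    scenarios: Optional[Sequence[tuple[str, int]]] = None  # None = all


@dataclass
class StudyResult:
    bundle: synth.LandscapeBundle
    occ: "object"
    distance_stats: dict
    retained: list[str]
    fit: enm.FittedENM
    climate_1to10: "object"
    boyce_climate: float
    boyce_weighted: float
    contributions: dict[str, float]
    weighted_current: "object"
    weighted_future: dict
    suitability_change_pct: dict
    pairwise: circuits.PairwiseResult
    scci_mean: dict
    reachable: list[dict]
    bat_overlap: overlap.OverlapMatrix
    gap: pd.DataFrame


def run_study(seed: int, config: Optional[StudyConfig] = None) -> StudyResult:
    cfg = config or StudyConfig()
    bundle = synth.generate_landscape(
        seed=seed,
        extent=cfg.extent,
        resolution=cfg.resolution,
        n_predictors=cfg.n_predictors,
        n_occurrences=cfg.n_occurrences,
    )
    names = bundle.predictor_names

    # -- occurrence prep ----------------------------------------------------
    occ = assign_longitude_groups(filter_records(bundle.occurrences.records))
    dstats = pairwise_distance_stats(occ)

    # -- predictor screen and training table --------------------------------
    pa = enm.sample_disk_pseudoabsences(
        occ, bundle.current_stack[0], n=cfg.n_pseudoabsences,
        r_min_km=cfg.r_min_km, r_max_km=cfg.r_max_km, seed=seed,
    )
    all_lons = np.concatenate([occ.lons, pa["lon"].to_numpy()])
    all_lats = np.concatenate([occ.lats, pa["lat"].to_numpy()])
    Xfull = enm.extract_stack_values(bundle.current_stack, names, all_lons, all_lats).dropna()
    retained, _ = enm.vif_select(Xfull, threshold=cfg.vif_threshold)
    sel = [g for g, n in zip(bundle.current_stack, names) if n in retained]
    table = enm.build_training_table(occ, pa, sel, retained)

    # -- tune, fit, evaluate -------------------------------------------------
    fit = enm.tune_and_fit(table, cfg.tuning, seed=seed)
    pres_pred = fit.predict_table(table.X[table.y == 1])
    back_pred = fit.predict_table(table.X)
    boyce_climate = evaluation.evaluate_boyce(pres_pred, back_pred)
    contributions = evaluation.variable_contributions(fit)

    # -- projection: current and MEDI-combined futures -----------------------
    current_map = projection.project_model(fit, sel, retained)
    climate_1to10 = projection.reclassify_suitability(current_map)

    scenarios = cfg.scenarios or [(s, y) for s in synth.SSPS for y in synth.YEARS]
    gcms = bundle.truth.gcms
    medi_future: dict[tuple[str, int], projection.SuitabilityMap] = {}
    for ssp, year in scenarios:
        maps, mess_maps = [], []
        for gcm in gcms:
            stack = bundle.future_stacks[(ssp, year, gcm)]
            sel_f = [g for g, n in zip(stack, names) if n in retained]
            maps.append(projection.project_model(fit, sel_f, retained, scenario=(ssp, year, gcm)))
            mess_maps.append(projection.compute_mess(table.X[retained], sel_f, retained))
        medi_future[(ssp, year)] = projection.combine_medi(maps, mess_maps)

    # -- couple-and-weigh overlay --------------------------------------------
    pref = overlay.elevation_preference_curve(occ, bundle.dem)
    elev_1to10 = overlay.reclassify_dem(bundle.dem, pref)
    rivers_1to10 = overlay.river_functionality_index(bundle.rivers, bundle.dem)
    weighted_current = overlay.weighted_overlay(
        climate_1to10, elev_1to10, rivers_1to10, cfg.overlay_weights
    )
    weighted_future = {
        key: overlay.weighted_overlay(
            projection.reclassify_suitability(m), elev_1to10, rivers_1to10, cfg.overlay_weights
        )
        for key, m in medi_future.items()
    }
    pres_w = weighted_current.value_at(occ.lons, occ.lats) / 10.0
    back_w = weighted_current.values[weighted_current.mask] / 10.0
    boyce_weighted = evaluation.evaluate_boyce(pres_w[np.isfinite(pres_w)], back_w)

    # percent change of weighted suitability sampled at the occurrences
    cur_at_occ = weighted_current.value_at(occ.lons, occ.lats)
    ok = np.isfinite(cur_at_occ)
    change = {}
    for key, wmap in weighted_future.items():
        fut_at_occ = wmap.value_at(occ.lons, occ.lats)
        both = ok & np.isfinite(fut_at_occ)
        change[key] = float(
            100.0 * (fut_at_occ[both].mean() - cur_at_occ[both].mean()) / cur_at_occ[both].mean()
        )

    # -- connectivity ---------------------------------------------------------
    rng = np.random.default_rng([seed, 23])
    n_focal = min(cfg.n_focal_pairwise, len(occ))
    pick = rng.choice(len(occ), size=n_focal, replace=False)
    focal = [(occ.lons[i], occ.lats[i]) for i in pick]
    g_now = circuits.raster_to_graph(weighted_current)
    pairwise_now = circuits.solve_pairwise(g_now, focal)

    forests = [overlay.forest_point_to_polygon(f) for f in bundle.forests]
    ground_polys = [f.polygon for f in forests]
    sources = [((lon, lat), 1.0) for lon, lat in focal]
    adv_now = circuits.solve_advanced(g_now, sources, ground_polys)
    scci_mean = {}
    for key, wmap in weighted_future.items():
        g_fut = circuits.raster_to_graph(wmap)
        adv_fut = circuits.solve_advanced(g_fut, sources, ground_polys)
        scci = circuits.compute_scci(adv_now, adv_fut)
        scci_mean[key] = float(np.nanmean(scci.values))

    reachable = circuits.classify_reachable_forests(forests, occ, radius_km=cfg.forest_buffer_km)

    # -- niche overlap and gap analysis ---------------------------------------
    group_sets = []
    env_at_occ = enm.extract_stack_values(sel, retained, occ.lons, occ.lats)
    for gname in ("West", "Central", "East"):
        members = [i for i, r in enumerate(occ.records) if r.group == gname]
        pts = env_at_occ.iloc[members].dropna().to_numpy()
        if len(pts):
            group_sets.append(overlap.EnvPointSet(gname, pts))
    bat_overlap = overlap.overlap_matrix(group_sets, kernel="linear") if len(group_sets) >= 2 else overlap.OverlapMatrix(labels=[s.label for s in group_sets])

    gap = overlap.gap_analysis(occ, bundle.protected, forests)

    return StudyResult(
        bundle=bundle,
        occ=occ,
        distance_stats=dstats,
        retained=retained,
        fit=fit,
        climate_1to10=climate_1to10,
        boyce_climate=boyce_climate,
        boyce_weighted=boyce_weighted,
        contributions=contributions,
        weighted_current=weighted_current,
        weighted_future=weighted_future,
        suitability_change_pct=change,
        pairwise=pairwise_now,
        scci_mean=scci_mean,
        reachable=reachable,
        bat_overlap=bat_overlap,
        gap=gap,
    )
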