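#!/usr/bin/env python
"""Project the tuned model to current and future climates, quantify
extrapolation with MESS, combine the per-GCM projections into a MESS-weighted
(MEDI) ensemble per SSP x horizon, and reclassify suitability to 1-10.

Writes results/04_projection/ (MEDI rasters plus a per-scenario summary).
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np

from noctule import enm, projection
from noctule.occurrences import filter_records
from noctule.pipeline import StudyConfig
from noctule.synth import SSPS, YEARS, generate_landscape


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/04_projection"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    warnings.simplefilter("ignore")
    cfg = StudyConfig()

    bundle = generate_landscape(seed=args.seed)
    occ = filter_records(bundle.occurrences.records)
    names = bundle.predictor_names
    pa = enm.sample_disk_pseudoabsences(occ, bundle.current_stack[0], n=cfg.n_pseudoabsences, seed=args.seed)
    lons = np.concatenate([occ.lons, pa["lon"].to_numpy()])
    lats = np.concatenate([occ.lats, pa["lat"].to_numpy()])
    Xfull = enm.extract_stack_values(bundle.current_stack, names, lons, lats).dropna()
    retained, _ = enm.vif_select(Xfull)
    sel = [g for g, n in zip(bundle.current_stack, names) if n in retained]
    table = enm.build_training_table(occ, pa, sel, retained)
    fit = enm.tune_and_fit(table, cfg.tuning, seed=args.seed)

    current = projection.project_model(fit, sel, retained)
    projection.reclassify_suitability(current).write_ascii(out / "current_1to10.asc")
    summary = {}
    for ssp in SSPS:
        for year in YEARS:
            maps, mess_maps, mess_neg = [], [], {}
            for gcm in bundle.truth.gcms:
                stack = bundle.future_stacks[(ssp, year, gcm)]
                sel_f = [g for g, n in zip(stack, names) if n in retained]
                maps.append(projection.project_model(fit, sel_f, retained, scenario=(ssp, year, gcm)))
                mm = projection.compute_mess(table.X[retained], sel_f, retained)
                mess_maps.append(mm)
                mess_neg[gcm] = float(np.mean(mm.grid.values[mm.grid.mask] < 0))
            medi = projection.combine_medi(maps, mess_maps)
            projection.reclassify_suitability(medi).write_ascii(out / f"medi_{ssp}_{year}_1to10.asc")
            mean_cur = float(np.nanmean(current.grid.values))
            mean_fut = float(np.nanmean(medi.grid.values))
            summary[f"{ssp}_{year}"] = {
                "mean_suitability_current": mean_cur,
                "mean_suitability_medi": mean_fut,
                "fraction_novel_cells_per_gcm": mess_neg,
            }
            print(
                f"{ssp} {year}: mean suitability {mean_cur:.3f} -> {mean_fut:.3f}; "
                f"novel-climate fraction per GCM {mess_neg}"
            )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
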