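# noctule

Habitat-suitability, landscape-connectivity and niche-overlap analyses for a
wide-ranging, forest-dependent bat (modelled on the giant noctule,
*Nyctalus lasiopterus*), packaged as a reusable pipeline that runs
end-to-end on synthetic landscapes with known ground truth.

## The problem

The giant noctule roosts in cavities of mature trees and commutes large
distances (daily foraging transits up to ~130 km), so its long-term
persistence depends jointly on (i) a suitable climate, (ii) rivers and
elevation belts it uses to move, and (iii) reachable old-growth forests.
This package implements the full analysis chain that links those pieces:

1. **Occurrence screening** — records older than 1970, coordinates coarser
   than 2.5 arc-min (positional uncertainty `0.5·10⁻ᵈ` degrees for *d*
   printed decimals), and cell duplicates are dropped; records are split
   into West / Central / East longitude groups (breaks −15°, 0°, 15°, 50°).
2. **Climate niche model** — predictors are screened by variance inflation
   factor (drop while max VIF ≥ 10); 5,000 pseudo-absences are drawn from a
   130–250 km great-circle annulus around the presences; presences are
   up-weighted so both classes carry equal total weight
   (`w⁺ = n⁻/n⁺`); a boosted-trees classifier (Bernoulli deviance) is tuned
   over a shrinkage × depth × node-size × bag-fraction grid by minimum
   cross-validated RMSE of predicted probability, and evaluated with the
   continuous Boyce index, variable contributions, Friedman's H interaction
   statistic and Moran's-I residual correlograms.
3. **Projection** — the model is projected to current and future rasters
   (2 SSPs × 3 horizons × 3 GCMs); extrapolation is measured per cell with
   MESS, and the per-GCM projections are combined into a MESS-weighted
   ensemble (weights `max(MESS, 0) + ε`); suitability is reclassified to a
   1–10 scale with `class(v) = min(⌊10v⌋ + 1, 10)`.
4. **Couple-and-weigh overlay** — an elevation preference curve (100-m
   bands, min–max rescaled occurrence counts → 1–10), a river
   connectivity-functionality index (`CSI − URB` over Strahler order > 4
   reaches → 1–10), and the climate classes are merged by a weighted
   overlay (default weights 0.5 / 0.25 / 0.25) into the weighted
   suitability map.
5. **Circuit connectivity** — the weighted map becomes an electrical
   network (cell conductance = suitability class, edge conductance = mean
   of the endpoints, diagonals ÷ √2). Pairwise mode solves every focal pair
   for effective resistance and cumulative current; advanced mode drives
   current from populations to old-growth-forest grounds. Change between
   scenarios is summarized by the standardized connectivity change index
   `SCCI = (F − C)/(F + C) ∈ [−1, 1]`. Forests within 130 km of a
   population are flagged reachable.
6. **Overlap & gap analysis** — niche overlap between groups is decided by
   perfect SVM separability (near-hard margin; linear or 2nd-degree
   polynomial kernel), and occurrences are intersected with Natura 2000 /
   national protected areas and scored by distance to the nearest forest.

Because the original climate, elevation and land-cover sources are
multi-gigabyte downloads, the package ships a synthetic-landscape generator
(`noctule.synth`) producing spatially autocorrelated, partially collinear
predictors, GCM-perturbed futures, a river network with Strahler/CSI/URB
attributes, forests, protected areas, and occurrences sampled from a known
logistic suitability — so every step is testable against ground truth.

## Worked example

```bash
python analysis/02_prepare_occurrences.py --seed 1
```

prints

```
260/260 records kept; drops: {'year': 0, 'precision': 0, 'duplicate': 0, 'outside_group': 0}
mean pairwise distance 1400 km, median 1397 km (33670 pairs); groups: {'Central': 96, 'East': 115, 'West': 49}
```

i.e. all 260 synthetic records survive the screening (they are generated
with full-precision, post-1990 coordinates), populations are spread over
~1,400 km on average, and the three longitude groups are all populated.
Fitting and evaluating the niche model:

```bash
python analysis/03_fit_enm.py --seed 1
```

```
VIF screen kept ['P0', 'P1', 'P2', 'P3', 'P4'] (removed ['P5'])
best parameters: {'shrinkage': 0.1, 'interaction_depth': 3, 'min_obs_in_node': 10, 'bag_fraction': 0.8, 'n_trees': 250} (CV RMSE 0.2434)
Boyce index 0.790; contributions (%): P0=47.6, P1=28.4, P2=14.8, P3=5.1, P4=4.1
strongest interaction: P0-P1 (H = 0.210)
```

The VIF screen removes one member of the generated collinear pair
(P4–P5, r = 0.95), and the fitted contributions recover the generating
truth: P0 — the predictor with the largest |β| — tops the ranking. The
remaining drivers (`analysis/04…07`) project futures, build the weighted
overlay, solve the circuit models and run the overlap/gap analyses, each
writing tables under `results/`.

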