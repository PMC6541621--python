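# mrdsurvey

Abundance and habitat inference for **double-observer aerial line-transect
surveys** of coastal dolphins. Two observer platforms (mid- and rear-seat)
record schools independently along systematic transects; this package turns
those paired sighting streams into stratified abundance estimates and a
habitat-driven density surface:

* duplicate resolution between the tandem platforms and declination-angle →
  perpendicular-distance geometry;
* **mark-recapture distance sampling (MRDS)** with point independence:
  a covariate-scaled detection function g(x) (half-normal or hazard-rate key)
  fitted by maximum likelihood to the pooled distances, and conditional
  logistic mark-recapture models giving the trackline detection probability
  p(0) = 1 − (1 − p(0)₁)(1 − p(0)₂) that conventional distance sampling
  assumes to be 1;
* stratified **Horvitz–Thompson** estimation,
  N̂ = (A / 2wL) Σᵢ sᵢ/p̂ᵢ with p̂ᵢ = p(0)·eswᵢ/w, with detection (delta
  method) and encounter-rate (between-transect, lines as sampling units)
  variance components and log-normal confidence intervals;
* a **Tweedie GAM** habitat model on 5-km effort segments — penalized
  cubic-spline smooths of depth, sea-floor slope, mean SST and distance
  layers, double-penalty shrinkage so uninformative terms drop out, the
  Tweedie power p ∈ (1, 2) profiled by exact compound Poisson–gamma
  likelihood — with family comparison by randomized-quantile-residual
  normality and spatial prediction per 37-km² cell;
* a **synthetic survey simulator** (strata, transects, environmental
  rasters, schools, double-platform detections) with known truth behind
  every estimator.

Model-fitting components follow the scikit-learn estimator convention
(`fit`, fitted attributes with trailing underscores, `get_params`), so they
compose with sklearn tooling; module-level functions wrap them for
script use.

## Worked example

```python
import mrdsurvey as m

# a full synthetic survey: 4 strata totalling 42,437.8 km^2, systematic
# transects at 7.5 km spacing, two platforms, known truth
sim = m.simulate_survey(m.SimulationConfig(seed=1))
print(len(sim["mid"]), len(sim["rear"]), sim["truth"]["n_animals"]["total"])
# 129 84 3639

res = m.estimate_survey(sim["mid"], sim["rear"], sim["effort"], sim["strata"])
pooled = res["pooled"]
print(f"N = {pooled.n_animals:.0f}  CV = {pooled.cv_animals:.2f}  "
      f"95% CI = ({pooled.ci_animals[0]:.0f}, {pooled.ci_animals[1]:.0f})")
# N = 4050  CV = 0.10  95% CI = (3308, 4958)
print(res["ds"].form, round(res["mr"].p0_combined_, 2))
# half_normal 0.92
```

The survey seeded with 1 realises 3,639 animals; duplicate matching,
truncation to the 71–570 m window, the MRDS fit and stratified
Horvitz–Thompson scaling estimate 4,050 with a 95% interval that covers the
truth. `res["per_stratum"]` holds the per-stratum rows (abundance, density,
mean school size, CVs, intervals) in the usual seasonal-report layout.

The same stages are available from the shell:

```bash
mrdsurvey simulate --seed 1 --outdir survey/
mrdsurvey estimate --mid survey/sightings_mid.csv --rear survey/sightings_rear.csv \
    --effort survey/effort.csv --strata survey/strata.geojson --outdir est/
mrdsurvey habitat --transects survey/transects.csv \
    --sightings est/unique_sightings.csv --raster survey/raster.csv --outdir hab/
```

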