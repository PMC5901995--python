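# seismove

Predator movement analysis relative to regenerating seismic lines — the
narrow (~8 m) linear clearings cut through boreal forest for oil and gas
exploration. Seismic lines facilitate movement of wolves and grizzly bears
through caribou range; whether natural vegetation regrowth on a line is
enough to stop predators treating it as a travel corridor is a central
question for caribou habitat restoration. `seismove` implements the
two-scale analysis used to answer it, for movement ecologists working with
GPS telemetry and a LiDAR-derived vegetation-height raster:

- **Broad scale — step selection functions (SSF).** Each observed movement
  step is compared with K = 10 random steps sharing its start point
  (lengths and turn angles resampled from the observed movement
  distributions). Conditional logistic regression estimates selection
  coefficients for line covariates, maximising

  `L(β) = Σ_s w_s [ βᵀx_used(s) − log Σ_{j∈s} exp(βᵀx_j) ]`

  with PFix weights `w_s` (inverse probability of a successful GPS fix).
  Covariates are decay-transformed distance to the nearest line segment
  (`eDist = 1 − e^(−0.002·d)`, saturating beyond ~2 km), segment vegetation
  height (*Veght*, m), decayed depth-to-water (`eWAM = 1 − e^(−1.55·w)`,
  saturating beyond ~3 m), line density (km/km², 1-km moving window), and
  landcover class (Conifer / Mixed / Non-forest). Candidate models M1–M5
  (eDist alone through eDist × Veght × fLand) compete on QIC_U with Akaike
  weights; per-individual fits are pooled by inverse-variance weighting
  with cluster-robust (sandwich) standard errors over independent step
  clusters (5 days for wolves, 24 h for bears); predictive skill is scored
  by k-fold rank-frequency cross-validation (r_s1 for used steps, r_s0 for
  a random available step).

- **Fine scale — movement rates near lines.** Steps ending within 100 m of
  a line enter Gaussian random-intercept mixed models of ln(rate, m/h) on
  ln(Veght + 1) × season × forest (M6–M8, compared by AICc, fit quality as
  marginal/conditional R²), followed by a post-hoc two-segment hinge
  regression locating the vegetation height at which the rate–height slope
  changes, with a 1,000-replicate case-resampling bootstrap CI.

Because the original telemetry and LiDAR are proprietary, the package
ships a first-class synthetic generator (`seismove.synthetic`): seismic
line networks at a target density (default 1.45 km/km²) whose ~100-m
segments carry right-skewed vegetation heights (default mean 0.81 m, 75%
below 1 m), wetness, landcover and density; biased correlated random-walk
tracks whose endpoint choice follows `exp(βᵀx)` over a 50-candidate set;
injected stationary bouts; Bernoulli fix thinning with 1/PFix weights; and
hinge-shaped movement-rate tables. Every generator records its ground
truth, so estimation is testable end to end.

## Worked example

Simulate a cohort of wolves on a known landscape with attraction to
low-vegetation lines (β_eDist = −1, β_eDist:Veght = +0.5) and recover the
coefficients:

```python
import pandas as pd
import seismove as sm

landscape = sm.make_landscape(seed=1, extent_km=5.0)
truth = sm.SimulationTruth(beta={"eDist": -1.0, "eDist:Veght": 0.5}, seed=3)
tracks = [sm.simulate_ssf_track(landscape, truth, n_steps=300,
                                animal_id=f"w{i:02d}", seed=100 + i)
          for i in range(8)]
steps = pd.concat([sm.build_steps(t) for t in tracks], ignore_index=True)
strata = sm.build_strata(steps, landscape.seg_index, K=10, seed=7,
                         extent=landscape.extent)
fit = sm.fit_clogit(strata, sm.SSF_MODELS["M2"])
cv = sm.kfold_cv(strata, sm.SSF_MODELS["M2"], reps=100, seed=7)
```

This prints (via the obvious formatting):

```
377 line segments, 2392 strata
  eDist        -1.002  (SE 0.162)
  Veght        -0.021  (SE 0.024)
  eDist:Veght  +0.467  (SE 0.070)
k-fold CV: r_s1 = 0.759, r_s0 = +0.047
```

The negative `eDist` coefficient says steps end closer to lines than
availability predicts (selection *for* lines); the positive interaction
weakens that attraction as segment vegetation height grows; the spurious
`Veght` main effect sits at zero. High r_s1 with near-zero r_s0 means the
model ranks real steps well while a random available step carries no
signal — the signature of a predictive SSF.

The fine-scale arm, on simulated rates that slow above a 0.7-m breakpoint:

```python
truth = sm.SimulationTruth(beta={}, breakpoint=0.7, seed=11)
table = sm.simulate_rate_data(truth, n_obs=300, noise_sd=0.3,
                              intercept_sd=0.2, seed=11)
est = sm.estimate_breakpoint_m(table, n_boot=1000, seed=1)
```

```
breakpoint 0.65 m (95% CI half-width 0.23 m), slopes +0.05 / -1.93
```

— flat below the kink, declining above it, with the true 0.7 m inside the
interval.

There is also a CLI for file-based runs
(`seismove synth | attribute | ssf | rate | all`); `seismove synth` writes
a complete bundle (fix CSV, attributed line GeoJSON, Esri ASCII rasters)
that the analysis subcommands consume.

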