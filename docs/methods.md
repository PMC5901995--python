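# Methods

## The estimation problem

Two behavioural signals are extracted from GPS telemetry of wolves and
grizzly bears around regenerating seismic lines, at two spatial scales.

At the **broad scale**, movement is summarised as steps between
consecutive fixes at the nominal schedule (2 h wolves, 1 h bears). A step
selection function compares where an animal actually stepped with where it
could have stepped: each used step is matched with K = 10 available steps
from the same start point, built by resampling step lengths and turn
angles (independently, with replacement) from the observed pools of the
same species–sex–season group. Independence of lengths and angles is
checked beforehand with a Spearman gate (warn above |ρ| = 0.115). The
conditional logistic likelihood for stratified data

    L(β) = Σ_s w_s [ βᵀx_used(s) − log Σ_{j∈s} exp(βᵀx_j) ]

is maximised by Newton iterations with step-halving, starting at β = 0,
declaring convergence at gradient max-norm < 1e-8 (max 50 iterations).
Rank deficiency of the within-stratum centred design and separation (a
coefficient escaping past |β| = 30 while the gradient flattens) are hard
errors, named after the offending covariate. The naive covariance is the
inverse observed information; the reported covariance is the cluster
sandwich A⁻¹BA⁻¹, where B sums outer products of per-stratum scores over
independence clusters of steps. Cluster boundaries fall where the time
since the previous step, or the span since the cluster began, exceeds the
species gap (5 days wolves, 24 h bears — the rolling-span rule is what
bounds bear clusters under continuous hourly sampling).

Candidate models M1–M5 are full factorials of eDist with Veght and one of
{nothing, eWAM, Density, fLand}; interactions always include their main
effects; fLand enters as reference-cell dummies against Non-forest. They
compete on QIC_U = −2ℓ + 2p at the population level (pooled strata), with
weights ω_i ∝ exp(−Δ_i/2). The selected model is refit per individual and
pooled per coefficient by inverse robust-variance weighting,
β̂_k = Σᵢ(β̂ᵢₖ/vᵢₖ)/Σᵢ(1/vᵢₖ), with 95% half-width 1.96·(Σᵢ1/vᵢₖ)^(−1/2).
Wolves additionally pass a pack filter first: contemporaneous same-pack
steps whose start points form a within-200-m connected component are
reduced to one uniformly chosen representative.

Validation is k-fold rank-frequency cross-validation: 100 repetitions of
an 80/20 stratum split; in each test stratum the 11 member scores are
ranked (average ranks on ties, binned by rounding); the frequency of each
rank among used steps, Spearman-correlated with the rank index, gives
r_s1. For r_s0 a uniformly drawn available step plays the used role and is
ranked **among the available steps only**, so its rank is uniform by
construction and r_s0 centres on zero under any model. (Ranking the
pseudo-used step among all eleven members instead would inherit the used
step's rank surplus and push r_s0 systematically negative under a
predictive model — measurably, to about −0.3 in our simulations — which is
why the available-only convention is the default; it is the one that makes
r_s0 a null reference.)

At the **fine scale**, steps ending within 100 m of a line (animals with
at least 20 such locations per season) enter Gaussian random-intercept
mixed models of ln(rate, m/h) — wolf 2-h displacements are halved to m/h —
on ln(Veght+1) × season × forest (M6 season-only, M7 adds the height
interaction, M8 adds forest). Variance components are REML; the AICc used
to compare fixed structures comes from a matching ML fit (the standard
convention, since REML likelihoods are not comparable across fixed
effects). AICc = −2ℓ + 2p + 2p(p+1)/(n−p−1). Fit quality is the
variance-partitioning R² for mixed models: marginal = var(fixed
predictor)/total, conditional adds the random-intercept variance to the
numerator. The post-hoc breakpoint is a two-segment continuous hinge,
fit by scanning candidate breakpoints over the observed covariate values
in the central 90% of the range and solving the 3-parameter OLS at each
(evaluated in closed form from prefix sums, so the scan is O(n log n));
the 95% CI is a case-resampling percentile bootstrap (1,000 replicates,
α = 0.05), reported as a half-width about the point estimate. The hinge
is fit on u = ln(Veght+1), the scale the mixed models use, and mapped back
to metres (e^u − 1), so the breakpoint is reported on the vegetation
height scale.

## Line attribution

The line network is cut into ~100-m segments: exact 100-m pieces, with a
terminal remainder folded into the last piece when shorter than 50 m
(lengths thus sit in [50, 150] m apart from whole lines shorter than
that). Per segment:

- **Veght** — mean raster height along the least-cost path between the
  segment's endpoint cells, Dijkstra over 8-connected cells within a
  corridor of the segment, cost = cell height + 1e-6·distance (the ε term
  breaks ties toward shorter paths). This follows the lowest vegetation —
  game trails — rather than averaging regrown flanks, and never exceeds
  the plain corridor mean when the corridor contains a contiguous low
  lane, the situation it is designed for. The cells the segment itself
  crosses are always included, so the corridor stays connected even when
  the halfwidth (default 5 m, matching ~8-m line width against a fine
  LiDAR raster) is below the cell size.
- **eWAM** — 1 − e^(−1.55·depth-to-water), sampled at the segment
  midpoint; monotone, zero at saturated soil, ~constant beyond 3 m.
- **fLand** — the class (Con/Mix/NF) intersecting the greatest length of
  the segment, by exact segment-by-cell intersection; ties break to the
  declared class order and are logged. The rate models binarise this to
  forest = Con∪Mix.
- **Density** — total line length in a circular 1-km window centred on
  each cell, divided by the window area (km/km²).

Step covariates use the step **end point** only (no along-step sampling):
eDist = 1 − e^(−0.002·d) with d the distance to the nearest segment, plus
that segment's attributes. Nearest-segment queries run through an STRtree
and are tested to agree exactly with brute force.

## The synthetic generator

The generator emulates the study conditions, not the study's geography:

- **Landscape** (default 5 × 5 km, 30-m rasters): long parallel transects
  carrying ~70% of the target line length plus random cross-lines (density
  contrast for the Density covariate), at 1.45 km/km² total. Segment
  vegetation heights are gamma with mean 0.81 m and shape solved (on the
  right-skewed small-shape branch) so that 75% of segments fall below 1 m.
  The height raster is tall-forest background with the segment heights
  burnt in along the lines; wetness is a smooth 0–5 m field; landcover is
  a smoothed field split ~50/25/25 into Con/Mix/NF.
- **Tracks**: biased correlated random walks. Step lengths are gamma
  (shape 2, scale 150 m — a right-skewed ~300-m mean appropriate to 1–2-h
  fixes), turn angles von Mises (κ = 1) about the previous bearing; both
  configurable, since the field workflow uses empirical distributions. At
  each step, 50 candidate endpoints are drawn and one chosen with
  probability ∝ exp(βᵀx); the candidate set is deliberately much larger
  than the K = 10 used in fitting so the generative weighting approximates
  the continuous selection kernel. Endpoints leaving the extent reflect at
  the boundary.
- **Availability must respect the same boundary.** Available endpoints in
  `build_strata` are reflected into the study extent when one is supplied.
  Without this, availability near edges systematically overstates
  distance-to-line relative to the reflected movement process, and a null
  (β = 0) simulation yields a spurious attraction of about β̂ ≈ −0.7; with
  reflection the null recovers zero. For field data with an irregular
  study area the extent can be omitted (no reflection), which reproduces
  the common practice of leaving availability unconstrained.
- **Stationary bouts**: a bout inserts ceil(duration/interval) + 1 fixes
  at the nominal schedule, jittered within half the bout radius of the
  anchoring fix, so the run spans strictly more than the bout duration —
  the way a real bout of that length presents to a strictly-greater-than
  classifier — and stays within the radius of the run centroid. Truth
  labels are recorded for recall/precision tests.
- **Fix thinning**: Bernoulli retention at PFix (study means ~0.5);
  retained fixes carry weight 1/PFix. The upstream fix-success regression
  models are out of scope; PFix is an input column defaulting to 1.
- **Rate tables**: log-rate = intercept + hinge(ln(Veght+1); kink at
  ln(1+0.7), slopes 0 / −2) + N(0, 0.2²) individual intercepts +
  N(0, 0.3²) noise, Veght from the landscape's gamma.

What the generator does **not** emulate: real geography (projections,
rivers, terrain), empirical per-group step-distribution shapes (one kernel
per track), multi-species interaction, habitat-dependent fix failure, or
temporal autocorrelation in rates beyond the individual intercept. Passing
tests therefore demonstrate that the estimators recover known structure
under the stated model, not that the model is adequate for any particular
field dataset.

## Stationary classification

The field workflow used an unpublished GIS clustering tool; here the rule
is made explicit: a maximal run of consecutive fixes is stationary iff its
time span exceeds the species threshold (6 h wolves, 7 h bears) and every
fix lies within the species radius (300 m / 100 m) of the run centroid.
Runs grow greedily from the earliest unlabelled fix, making labels
deterministic. Every fix is exactly one of movement/stationary, and the
label count is monotone in both thresholds.

## Numerical choices and degenerate inputs

- Rarefaction keeps the first fix of each gap-run and never invents fixes;
  spacing tolerance defaults to 5 min.
- A step's turn angle needs the previous retained step to end where it
  starts; first steps carry no angle and cannot seed availability — their
  strata are skipped and logged.
- Steps spanning a season boundary take the start fix's season.
- Collinearity screening drops the later-listed member of any |r| > 0.6
  pair, then iterates VIF > 3 removals; all decisions are reported.
- The weighted conditional likelihood treats PFix weights per stratum; a
  weight-2 stratum is exactly equivalent to duplicating it (tested
  algebraically).
- The hinge scan's normal equations carry a 1e-10 ridge so candidates with
  a degenerate side return a finite (large) SSE instead of failing.
- Bootstrap replicates that cannot support a hinge fit are skipped; more
  than 20% failures aborts the interval.
- Mixed-model singular random structures pin the variance near zero with a
  warning rather than failing; empty design cells give NaN standard errors
  for exactly those terms.

## Design choices that were genuinely open

- *QIC_U form*: −2ℓ + 2p on the pooled fit, without a robust-trace
  correction; documented rather than asserted to match any particular GEE
  implementation.
- *"Inverse-weighted" pooling* is read as inverse robust-variance
  weighting per coefficient, the standard two-stage population estimator
  consistent with reporting β ± 95% CI. The two-stage estimator shrinks
  mildly toward zero in small samples (variance estimates correlate with
  coefficient estimates), so recovery checks are anchored on the pooled
  one-stage fit and the two-stage pooling is verified for sign and a wider
  band.
- *r_s0 convention*: see above; the pseudo-used draw is configurable.
- *Breakpoint machinery*: an explicit grid-search hinge with a percentile
  bootstrap replaces opaque smoothing-based alternatives; every step of
  the declared estimator is testable against exhaustive scans.
- *ML vs REML*: REML variances, ML-based AICc across fixed structures.
- *M4 (Density) stays in the candidate set* for completeness even where no
  analysis selects it.
- Wolf movement-rate data are restricted to females, and wolf SSFs pool
  sexes, via configuration filters rather than hard-coded rules.

## Problem sizes

The bundled checks run at desk scale: recovery cohorts of 20 animals ×
300 steps (≈6,000 strata) on a 5-km landscape, 10–20 replicate cohorts
for sign recovery, 100 cross-validation repetitions, 100 simulated
datasets × 1,000 bootstrap replicates for breakpoint coverage, and a
40 × 50 mixed-model design. These sizes give Monte-Carlo standard errors
comfortably inside the tolerances being asserted while keeping the full
suite in a couple of minutes.

## Known limitations

- The least-cost mean can exceed the corridor mean on adversarial rasters
  with no low lane (e.g. forced high endpoints); the invariant is
  guaranteed only for corridors containing a contiguous low lane.
- The generative/inferential agreement carries an O(1/M) bias from the
  finite 50-candidate set and a small contamination from selection-biased
  empirical pools; at the default settings both are well inside two
  Monte-Carlo standard errors.
- Line density is exact per window but computed per cell; the landscape
  generator evaluates it on a coarser (150-m) grid and samples segment
  midpoints, trading resolution for speed.
- No multi-breakpoint models, no temporal autocorrelation structures, no
  integrated SSF movement-kernel estimation, no home-range estimation.
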