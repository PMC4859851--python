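# Methods

## The analysis in brief

Brown bears in boreal production forests feed almost exclusively on berries
during hyperphagia. The package asks, with GPS telemetry and quadrat
inventories, whether bears *select* foraging locations with more / better
berries than the landscape offers at random, species by species, and whether
that selection tracks the seasonal hand-over from bilberry (declining through
late August) to lingonberry (ripening through early September).

The design is used–available: 1-m² berry quadrats at positions where
classified foraging occurred ("used") are compared with quadrats at uniform
random positions ("available"), sharing one model family so that a plot-type
indicator (random = 0, bear = 1) measures selection after adjusting for
habitat and terrain.

## Trajectory classification

Collars schedule a fix every 30 min (48/day). Berry foraging is slow and
continuous, so a foraging bout is defined as a **maximal run of ≥ 3
consecutive fixes whose every 30-min step lies in [25, 300] m**. A failed fix
leaves the step before and after it undefined; undefined steps terminate runs
and are never bridged. Berry plots are sampled at the run's second fix, plus
the second-to-last fix for runs of ≥ 7 fixes (by then > 2 h of movement
separates the two samples, so their spatial autocorrelation is considered
low). Whole segments with any fix within 200 m (inclusive) of a known
attractant site are discarded.

Two readings of the 25–300 m rule are possible: per step (each interval in
band) or per trajectory (summed path length in band). Per-step is the default
— "consistently slow movement" is a property of every interval — and the
alternative is available via `find_foraging_segments(..., rule="path")`; under
the path rule maximality means "not contained in a longer qualifying window"
and windows may overlap.

## Plot placement

From each sampling position the quadrat centre is offset 0–9 m (the last
digit of the integer Y coordinate, in metres) in a cardinal direction chosen
by the last digit of the integer X coordinate. The digit→direction bijection
is not uniquely determined by the protocol description; any fixed bijection
is statistically equivalent, so the order (N, E, S, W by digit mod 4) is a
configurable convention. A quadrat showing signs of prior foraging is mirrored
through the GPS position (same distance, opposite direction), an involution
that keeps the placement distribution unbiased while avoiding depleted spots.

Covariates are read from co-registered raster layers by nearest-cell lookup
(no interpolation — habitat is categorical, and the continuous layers follow
the same convention for consistency; boundary ties break to the lower
row-major index). Plots in habitats outside the four modelled classes, and
plots with incomplete covariates, are dropped; each random plot is assigned a
bear id uniformly at random (seeded) so both plot types enter the same mixed
model.

## The hurdle mixed models

Berry counts are zero-inflated and overdispersed, so occurrence and abundance
are modelled separately (hurdle factorisation — the two likelihood parts are
independent and their log-likelihoods add):

* **Occurrence**: Bernoulli(count ≥ 1), logit link, on all plots.
* **Abundance**: zero-truncated NB2 on the occupied plots,
  `P(k) = NB(k; μ, θ) / (1 − (θ/(θ+μ))^θ)`, log link, variance μ + μ²/θ
  (θ estimated on the log scale jointly with the coefficients).

Both parts carry a **bear-id random intercept**: η = Xβ + σ·u, u ~ N(0, 1).
The marginal likelihood integrates u out by **adaptive Gauss–Hermite
quadrature**: per group the integrand mode is found by a vectorised 1-d
Newton search, the node grid is centred and scaled there, and node
contributions combine through a log-sum-exp. One node is exactly the Laplace
approximation. Default 10 nodes for reported fits; model-selection scans use
fewer (`RunConfig.selection_nodes`, default 5) since LR comparisons only need
consistent log-likelihoods across nested fits. The outer optimisation is
L-BFGS-B on an internally standardised design (coefficients and covariance
are mapped back to the original covariate scale afterwards); standard errors
come from the inverse observed information (central-difference Hessian at the
optimum), with parameters pinned at a bound (e.g. σ̂ → 0) excluded so the
information stays invertible. Convergence flags are honest: optimiser
failure, non-positive-definite information, or |coefficients| large enough to
indicate separation (binomial) mark the fit non-converged.

Full models contain plot type, habitat, the VIF-screened terrain covariates
(elevation, NDVI, slope, ordinal day; aspect as a factor), plus
habitat × plot type and date × plot type interactions. The VIF screen
(cut-off 3, iterated, largest first) is applied to the numeric covariates
only; categorical dummies are excluded from the screen. **Backward
selection** repeatedly removes the single least significant droppable term
(LR p > α = 0.05; interactions always drop before the main effects they
contain), refitting warm-started from the surviving coefficients, until every
remaining term is significant. Post-hoc pairwise contrasts of surviving
factor structure are single-step adjusted: p_adj,i = P(max_j |Z_j| ≥ |z_i|)
under the joint normal with the correlation implied by the coefficient
covariance, by seeded Monte Carlo (default 10⁵ draws; a single contrast is
returned exactly unadjusted). Population-level predictions set the random
intercept to zero, form Wald intervals on the link scale and transform them.

The seasonal-shift analysis stacks bilberry and lingonberry counts from the
same foraging quadrats (clearcut and mature forest only) in long format and
fits species × day × habitat with a **plot-id random intercept** (both
species were counted in the same quadrat). A plain NB family is the default
here — the response includes zeros; a truncated variant is available through
`RunConfig.seasonal_family`. Sugar content (TSS, %Brix) is Gaussian with a
bear-id random intercept, per species, same selection procedure, plus a
Welch t test (Satterthwaite df) between the species means — the t-test
variant is not uniquely implied by the protocol; Welch is the safer default
under unequal variances.

## The synthetic study generator

No field data ship with the package; the generator produces every input with
known truth. Its defaults are the study conditions:

* **Landscape**: 160×160 cells of 25 m; quota-limited region growth gives a
  patchy mosaic with shares clearcut 8 %, bog 10 %, young forest 42 %,
  mature forest 40 %; smooth elevation in [200, 600] m; slope and aspect from
  the elevation gradient; NDVI positively tied to young-forest density and
  clipped to [−1, 0.86].
* **Berry fields**: hurdle structure per species with coefficients echoing
  the field sign pattern — bilberry occurrence/abundance decline with ordinal
  day (−0.022 / −0.012 per day) and peak in mature forest; lingonberry rises
  (+0.07 / +0.028 per day) and peaks on clearcuts with a negative NDVI
  effect; crowberry is rare (≈ 10–15 % occupancy) and strongly overdispersed
  (θ = 0.3) and is generated but never modelled. Per-bear random intercepts
  (variance 0.2) create the grouping structure. Each species additionally has
  a **latent patchiness field** (SD ≈ 1.1 on the occurrence scale, 0.8 on the
  log-abundance scale, independent across species) with *sub-cell* grain:
  berry micro-patches are metre-scale — the very premise of the 0–9 m quadrat
  offset rule — so distinct raster cells carry essentially independent patch
  values, while a bear still perceives cell-to-cell variation. This is berry
  variation a bear can see but the mapped covariates do not carry. Selection *on this residual field* is what produces a plot-type
  effect in correctly adjusted models — without it, any used–available
  contrast would be fully explained by the covariates and the plot-type
  coefficient would be null by construction.
* **Sugar**: Gaussian TSS around ≈ 8.48 %Brix (bilberry) and ≈ 12.04 %Brix
  (lingonberry) at the covariate centres for a balanced used/available mix,
  residual SD 1.3, with a plot-type effect (+0.579) for lingonberry only.
* **Movement**: a pragmatic 3-state (rest / forage / travel) Markov walk on
  the 30-min lattice — step regimes < 25 m, 25–300 m (uniform 30–260 m), and
  > 300 m respectively; foraging step directions weight candidate bearings by
  exp(w · standardised expected bilberry count), default w = 2.0; each bear is
  anchored to an individual home-range centre (radius 900 m) so the seven
  bears occupy distinct, partly overlapping neighbourhoods and their plots
  sample many independent berry patches rather than a few shared hotspots;
  fix
  failures are i.i.d. with probability 0.08 (≈ 92 % fix success). It is not a
  fitted behavioural model; it only needs to produce the step-length regimes
  the classifier targets and a tunable degree of berry attraction. Defaults
  give ≈ 400 segments averaging ≈ 5.5 fixes from 7 bears over 28 days,
  matching the scale of the field campaign.

Everything is reproducible from (config, seed); `write_scenario` emits
telemetry CSV, ESRI ASCII grids, plot tables and a ground-truth JSON.

A second, direct generator (`sample_used_available`) draws covariates
independently and puts an *explicit* plot-type coefficient in the hurdle
predictors; it is the tool for parameter-recovery experiments, where the
estimand must equal a known constant (in the movement scenario the plot-type
effect is emergent, with no single true value).

### What the simulator does not emulate

Real telemetry has location error (~10 m), habitat-dependent fix failure, and
behavioural rhythms (diel cycles, day beds); real berry fields have
within-plant clustering, depletion by foraging, and year effects; real plot
inventories lag the GPS position by days. Passing tests therefore demonstrate
that the *pipeline and estimators* behave correctly under the stated
generating assumptions — not that those assumptions exhaust the structure of
field data.

## Numerical choices and limitations

* Quadrature: 10 nodes agree with 20 to < 1e-4 log-likelihood units on test
  fixtures; Laplace (1 node) is available but noticeably different for
  binomial responses with few groups.
* The LR statistic is clamped at zero (with a warning beyond tiny numerical
  slack) when a "full" fit fails to beat its reduced model.
* With only seven bears, the ML variance component is biased downward and
  the *intercept* of the occurrence model carries a finite-sample offset of
  order 0.1 on the logit scale; the explanatory-variable coefficients are
  unbiased in recovery simulations (checked at 250 replicates). This is a
  property of conditional ML with few grouping levels, shared by any GLMM
  fitter, and is why baseline intercepts should not be over-interpreted in
  studies of this size.
* Zero-truncated sampling uses inverse-cdf conditioning (uniform on
  [P(0), 1]), exact and fast for any (μ, θ).
* Backward selection tests one term at a time against the current model; when
  several terms exceed α the least significant is removed first. The order is
  a convention; with correlated candidates different orders can occasionally
  end in different final models.
* The single-step adjustment is Monte-Carlo based; with the default 10⁵ draws
  the adjusted p values carry ≈ 0.002–0.005 absolute noise.

## Problem sizes used by the test suite

The statistical acceptance checks run at sizes chosen for a single-CPU
budget: 1 000 random tracks for classifier equivalence; 250 replicates for
hurdle recovery (bias and pooled Wald coverage); 20 end-to-end pipeline
replicates for the selectivity pattern; 25 replicates for the seasonal-shift
sign; 1 000 simulated fits for LR calibration. The thresholds
(5 % bias, [90, 98] % coverage, 90 % / 15 % retention bounds,
[0.03, 0.07] rejection band) are properties of the method, not of the chosen
replicate counts.
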