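# Methods

## The estimation problem

Two estimators of black bear density are implemented over one
non-invasive genetic sampling design: detectors (rub objects, fence
lines, and a coarse grid of opportunistic cells) record binary
per-occasion detections of identified individuals. Spatially explicit
capture–recapture (SECR) treats each animal's home-range center as a
latent point and models detections as a declining function of the
distance between center and detector; a resource-selection-function
(RSF) route converts relative habitat selection into density by
anchoring on a reference area with an independent abundance estimate.
Both are exercised on synthetic data with known generating parameters,
so every claim the test suite makes is a recovery or consistency
statement, not a comparison against field data.

## SECR model

Detection is hazard half-normal. For an animal centered at x and a
detector at distance d, the per-occasion cumulative detection hazard
is λ(d) = λ₀ exp(−d²/2σ²) and the detection probability
g(d) = 1 − exp(−λ(d)). λ₀ (expected detections per occasion at the
center) and σ (km) carry log-linear covariate effects:

- λ₀ — trap type (levels rub / fence / opp, reference rub), the
  trap-specific behavioral response **bk** (a 0/1 step switched on for
  a given animal–site pair from the occasion after the animal's first
  detection there), a linear time trend **T** (the 0-based occasion
  index; with seven systematic occasions plus one opportunistic
  occasion, T runs 0–7), a time-varying grizzly-presence indicator
  **GB**, and a categorical habitat **cover**.
- σ — trap type, T, GB.

Density over the habitat mask is log-linear:
D(x) = exp(z(x)′β_D), with land tenure entering as a categorical whose
reference level is protected land. Internally densities are bears/km²;
reports multiply by 1,000.

### Likelihood

With mask cells x_m of area a and per-cell naive (bk = 0) detection
hazards λ_ks(x_m), the probability that an animal centered at x_m is
ever detected is p·(x_m) = 1 − exp(−Σ_ks usage_ks λ_ks(x_m)). Writing
Λ = Σ_m D(x_m) a and Λp̄ = Σ_m p·(x_m) D(x_m) a, the Poisson full
likelihood is

−logL = Λp̄ − Σᵢ log Σ_m Pr(ωᵢ | x_m) D(x_m) a + log n!

where Pr(ωᵢ|x_m) is the product of per-detector-occasion Bernoulli
terms with the animal's own bk design. The binomial variant replaces
the Poisson count term with a binomial one using continuous N = Λ
through gamma functions, conditioning histories on detection. The
binomial count is conditioned on the mask-wide N (not per-region);
that choice is documented here because either reading is defensible.
Both forms agree with an independent brute-force enumeration oracle to
1e-8 on small instances (the oracle uses `expm1` for 1 − e^{−λ};
naive subtraction loses all precision when λ ≈ 1e−16).

Implementation notes: hazards are computed as a (detector × occasion
× cell) array; per-individual corrections touch only the sparse sets
of detected and bk-positive cells, so cost scales with detections, not
with the full tensor. Any linear predictor beyond ±50, a non-finite
likelihood, or a binomial Λ ≤ n returns a large barrier value that the
optimizer treats as infeasible.

### Fitting, starts, convergence

Maximization is L-BFGS-B on the working (log) scale with three starts:
ln σ at ln RPSV, ln λ₀ from the naive per-occasion capture rate via
the hazard link, ln D at ln(n / mask area), remaining coefficients 0;
the second and third starts jitter these by N(0, 0.3²). Convergence is
the optimizer's own criterion (projected-gradient tolerance 1e-5,
relative function tolerance ~1e-9); a fixed absolute gradient-norm cut
is unreliable with finite-difference gradients at |logL| of order 10³,
so the final projected-gradient norm is recorded on the result rather
than enforced. Standard errors come from the numerical Hessian
(inverse observed information); a singular Hessian leaves SEs absent
with a warning, never a silent success. `fixed=` pins named
coefficients for profile-likelihood work — the test suite uses it to
trace the λ₀–σ ridge, confirming the inverse compensation with a
density estimate that moves < 5% along it.

Wald CIs are computed on the log scale and exponentiated, which for D
is the conventional lognormal interval; RSE(D̂) is the SE of ln D̂
(delta method). AICc uses n = number of detected individuals — the
choice is validated against published model rows (LL = −1,750.67,
K = 8, n = 126 → 3,518.57; LL = −940.50, K = 9, n = 101 → 1,900.98,
both within the rounding of the printed log-likelihoods). Ties in
AICc resolve toward fewer parameters.

### Two-step selection and prediction

Step 1 fits the observation-model candidates (default: the 17-model
set spanning trap type, bk, T, GB, and cover effects) with D ~ 1 and
keeps the AICc-best; step 2 fits the density candidates (default:
eight single-covariate models — burn, tenure, harvest, tertiary
road, canopy, water, NDVI, road density) on that base. Candidate
failures are recorded per model and skipped. Density surfaces are
predicted per cell with delta-method CIs; regional abundance is the
discrete sum of D̂(x)·a over a region's cells, with CIs from 1,000
seeded parametric draws of β_D from its estimated covariance.

## RSF model

The exponential RSF score(x) = exp(β′x) omits the intercept (only
relative selection is identified in a used–available design). Fitting
is plain logistic regression (statsmodels) of used (1) against
available (0) rows; continuous covariates are standardized to mean 0,
SD 1 on the pooled design and the constants are stored so prediction
uses identical scaling; 0/1 covariates stay raw. Complete separation
(|standardized coefficient| > 30 or non-finite) and rank-deficient
designs raise errors naming the covariates. Candidate sets are chosen
by AIC, ties to fewer parameters.

"Scaled RSF scores" means division by the maximum score over the
domain — that makes every bin midpoint a number in (0, 1] as the
expected-use equation requires — followed by 10 equal-width bins on
[0, 1] (equal-width rather than quantile bins; the alternative would
change w(xᵢ) but not the conservation identities). U(xᵢ) =
w(xᵢ)A(xᵢ)/Σw(xⱼ)A(xⱼ) sums to 1 by construction; N̂ᵢ = N̂U(xᵢ) sums
back to the reference N̂ exactly, and both identities are asserted at
1e-9. The reference N̂ is the reference density × reference-area,
per sex; CI surfaces substitute the reference CI bounds for N̂ —
so the extrapolated CIs inherit only the reference uncertainty, not
the RSF's sampling error (a known understatement, flagged as a
limitation). Target cells whose bin is unpopulated in the reference
area borrow the nearest populated bin's density with a warning. An
area-of-inference helper drops the lowest bins (default three) when
the low tail is judged outside the model's support.

Cross-validation partitions used points into k folds (default 10×10
fold/repeats): each fold's model is refitted on the training folds,
the domain is re-binned on the refitted scores, and withheld points
are tallied per bin; Spearman correlation between bin rank and
area-adjusted frequency (frequency / bin area; a switch restores raw
frequencies) is averaged over folds, then over repeats. A
`refit=False` mode evaluates a fixed score surface, which the null
test uses with permuted scores.

## Synthetic study system

The generator emulates the study conditions rather than any one
landscape: a rectangular planar world (default 60 × 60 km ≈ the
3,600 km² study area) split into three contiguous tenure blocks with
shares 0.52 / 0.34 / 0.14 (private / Crown / protected); smooth
harmonic fields for NDVI-like productivity (0–1), canopy (0–100) and
road density; one burn disc covering 5% of the extent; piecewise
tenure-level harvest; ln-distance covariates from seeded linear
features. Rub and fence detectors sit jittered along the linear
features (surveys follow roads, trails and fences; a switch places
them uniformly), active on occasions 1..S−1; opportunistic detectors
at the centroids of 7 × 7 km cells, active only on the final
occasion. Populations are cell-wise Poisson draws from the log-linear
intensity with uniform placement within cells (Poisson rather than
fixed-N: the simplest process consistent with the intensity; the
fitter supports both count distributions). Captures follow the full
hazard model; bk is trap-specific and permanent within a session.
Detection-parameter defaults (λ₀ ≈ 0.03 at rub objects, σ = 3 km
females / 4 km males, bk ≈ +1.7 on the log scale, fence and
opportunistic offsets) sit in the range of the published per-trap-type
estimates; density defaults (~60 bears/1,000 km² at the protected
reference with negative private and Crown effects) likewise.

What the generator does *not* emulate: genotyping error and partial
individual identification, open-population turnover within a season,
spatial autocorrelation structure of real covariate rasters, real
road networks, and fence lines as extended transects (each fence
detector is a point; how fence segments were discretized into
detectors is not specified by the design being emulated). Passing
recovery tests therefore demonstrate internal statistical
correctness — the estimator recovers the parameters of the process it
assumes — not robustness to those field realities.

## Problem sizes in the test suite

Simulation tests run at sizes chosen to give stable pass/fail
behavior at desk scale: parameter-recovery uses 50 replicates of a
100-trap, 7-occasion array at D = 0.05/km², λ₀ = 0.1, σ = 2 km
(coverage ≥ 43/50 per parameter); CI calibration uses 100 replicates
of a 30-trap, 5-occasion array; two-step selection consistency uses
20 replicates with a generating Crown effect of −1; the bundled
end-to-end fixture uses ≤ 60 detectors and 6 occasions and reruns to
byte-identical artifacts. The published point estimates themselves
are not reproduction targets at these sizes — they would require the
original field dataset.

## Known limitations

- Wald/lognormal intervals only; no profile-likelihood or bootstrap
  CIs for SECR parameters.
- The binomial-N likelihood fixes N at the continuous Λ; integer-N
  conditioning is not implemented.
- RSF extrapolation CIs ignore selection-model uncertainty (reference
  CI only).
- Single-session estimation; multi-year trends, telemetry-informed σ,
  and non-Euclidean (least-cost) distance are out of scope.
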