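# beardensity

Density and abundance estimation for American black bears (*Ursus
americanus*) on a multi-use landscape, using two parallel methods over
the same non-invasive genetic sampling (NGS) design:

1. **Spatially explicit capture–recapture (SECR).** Binary detections
   of identified individuals at rub objects, fence lines, and gridded
   opportunistic samples are modeled with a *hazard half-normal*
   detection function. An animal whose latent activity center lies a
   distance *d* from a detector accrues cumulative detection hazard

   λ(d) = λ₀ · exp(−d² / 2σ²),  g(d) = 1 − exp(−λ(d)),

   where λ₀ is the hazard at the home-range center and σ the spatial
   scale (km). Activity centers are marginalized over a gridded
   habitat mask (buffer = 3 × RPSV, the root pooled spatial variance
   of detections), and density is log-linear in mask covariates —
   notably land tenure (private / Crown / protected, reference level
   protected). The full likelihood (Poisson or binomial prior on the
   number of centers) is maximized by quasi-Newton; model selection is
   a two-step AICc sweep (observation model under flat density first,
   density covariates second), with n = the number of detected
   individuals.

2. **Resource-selection-function (RSF) extrapolation.** An exponential
   RSF, score(x) = exp(β′x), is fitted by used–available logistic
   regression (detector locations with detections vs. the full
   detector set, 20:1 random:used for the placement-bias model).
   Max-scaled scores are cut into 10 equal-width bins with midpoints
   w(xᵢ) and areas A(xᵢ); the relative probability of use is

   U(xᵢ) = w(xᵢ)A(xᵢ) / Σⱼ w(xⱼ)A(xⱼ),

   and anchoring on a reference area assumed at carrying capacity with
   an independent abundance estimate N̂ gives per-bin abundance
   N̂ᵢ = N̂·U(xᵢ) and density D̂ᵢ = N̂ᵢ/A(xᵢ), extrapolated to the rest
   of the area of inference by bin membership. Predictive skill is
   measured by repeated k-fold Spearman cross-validation.

A first-class synthetic-data generator simulates the whole study
system — tenure mosaic, habitat covariates, detector arrays, an
inhomogeneous-Poisson bear population, and hazard half-normal
detections with trap-type, behavioral (bk), time-trend (T), and
grizzly-presence (GB) effects — so the full pipeline runs with known
generating parameters and no external data.

Intended users: quantitative wildlife ecologists and managers who
need SECR density surfaces, tenure-level abundances and sex ratios,
or a low-cost RSF-based extrapolation when only presence data are
affordable.

## Worked example

```python
import numpy as np
import beardensity as bd

cfg = bd.SimConfig(extent=(30, 30), n_rub=30, n_fence=8, seed=1)
landscape = bd.generate_landscape(cfg)
detectors = bd.place_detectors(landscape, cfg)

truth = bd.TrueParams(density_intercept=np.log(0.08), density_beta={},
                      lambda0=0.1, beta_bk=1.0)
population = bd.simulate_population(landscape, truth, seed=5)
history = bd.simulate_captures(population, detectors, truth, seed=6)
print(population.n_true, history.n_individuals)   # 74 48

rpsv = bd.compute_rpsv(history, detectors)
print(round(rpsv, 2))                              # 3.03
mask = bd.build_mask(detectors, 3 * rpsv, 2.0, clip_bounds=(0, 0, 30, 30))
mask = bd.attach_covariates(mask, landscape)

fit = bd.fit_secr(bd.ObservationModel((), ()), bd.DensityModel(()),
                  history, detectors, mask)
print({k: round(v["estimate"], 4) for k, v in fit.real_params().items()})
# {'D': 0.0695, 'lambda0': 0.0896, 'sigma': 3.7429}
```

74 bears were simulated at a true density of 0.08 bears/km² and 48
were detected at least once; the flat SECR model estimates 0.0695
bears/km² (69.5 bears/1,000 km²) with λ̂₀ = 0.09 and σ̂ = 3.7 km —
the generating values were 0.08, 0.1, and 3.0 (σ̂ absorbs the
unmodeled behavioral response in this deliberately misspecified flat
fit). `fit.real_params()` also carries 95% lognormal CIs, and
`bd.region_abundance` sums the density surface into per-tenure
abundances.

The same workflow end to end, including the RSF branch and the
comparison report:

```sh
beardensity report --config my_run.yaml --out runs/demo --seed 11
```

writes `report.csv` (method × sex × tenure densities per 1,000 km²
with CIs and abundances) and `sex_ratios.csv` (female:male abundance
ratios per tenure) plus all intermediate artifacts (TSV/CSV/JSON).
The YAML config can override the simulated design, the generating
parameters, the candidate model sets, and the reference densities;
without one, the defaults reproduce the full study-scale design (a
60 × 60 km landscape and the complete 17 + 8 candidate sweep), which
takes substantially longer than the small configs used in the test
suite.

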