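# occumap

Camera-trap survey analysis for elusive carnivores: from raw trigger
timestamps to a habitat-suitability map and a population bound.

`occumap` implements the full analytical chain used in single-season
occupancy studies of the European wildcat (*Felis silvestris*) and similar
mesocarnivores:

1. **Detection histories.** Raw triggers are collapsed into independent
   detections (a record counts only if ≥ 30 min after the previous record at
   that station) and binned into 5-day occasions anchored at each station's
   deployment start, giving the station × occasion 0/1/missing matrix.
2. **Royle–Nichols abundance model.** Detection heterogeneity is driven by
   latent abundance: station *i* hosts *N_i* ~ Poisson(λ_i) individuals with
   log λ_i = x_i′β; each individual is detected per occasion with
   probability r_i, logit r_i = w_i′α, so the station-level detection
   probability is 1 − (1 − r_i)^{N_i}. The marginal likelihood sums the
   latent count out to an adaptive truncation bound. Occupancy
   ψ = 1 − exp(−λ) and the species-level detection probability
   p = 1 − E[(1 − r)^N] are derived parameters. The MacKenzie constant-*p*
   single-season model is provided for the baseline comparison.
3. **Model building.** A three-step AIC workflow: detection structure first
   (survey-site factor, deployment duration), then univariate screening of
   abundance covariates against the null model plus collinearity pruning
   (|Pearson r| > 0.7, keeping the lower-AIC member), then an all-subsets
   run whose top models (cumulative Akaike weight 0.95) are averaged
   *conditionally* — each coefficient over the models that contain it, with
   an unconditional SE combining within- and between-model variance.
4. **Goodness of fit.** The MacKenzie–Bailey parametric bootstrap: a Pearson
   χ² over observed vs. expected detection-history frequencies, with the
   null distribution built by simulating from the fitted model and
   refitting; reports p and the overdispersion ratio ĉ.
5. **Prediction.** The averaged coefficients are applied to covariate grids
   (standardized with the training transform) to give a relative-abundance
   surface λ = exp(x′β̄), rescaled by its maximum into a 0–1 suitability
   index, reclassified into absent/low/medium/high density classes, and
   converted into a population bound via conservative density ranges
   (individuals/km²) per class.

A synthetic-survey generator (`occumap.simulate`) reproduces the
statistical structure of an eight-site, 292-station wildcat survey —
including 30-min-clustered raw triggers — so the whole pipeline runs and is
tested without any field data. The published per-site effort summaries and
density-class table of the northern-Greece wildcat survey ship in
`occumap.datasets` as real-world anchors for the summary arithmetic.

## Worked example

```python
import numpy as np
from occumap import (ModelSpec, RoyleNichols, build_history,
                     filter_independent, simulate_stations,
                     simulate_raw_records)
from occumap.simulate import SimulationConfig

cfg = SimulationConfig(n_sites=2, stations_per_site=100,
                       deployment_days=(40, 40),
                       beta={"(Intercept)": 0.0, "elevation": -0.6},
                       covariate_spec=(("elevation", "normal", (0, 1)),),
                       site_effects=[0.0, 0.3], seed=5)
deployments, covariates, truth = simulate_stations(cfg)
records = simulate_raw_records(truth, cfg)

independent = filter_independent(records, gap_minutes=30)
history = build_history(independent, deployments, window_days=5)

res = RoyleNichols(history, covariates,
                   ModelSpec(("elevation",), ("site",))).fit(seed=0)
print(res.summary())
```

prints

```
Royle-Nichols abundance/occupancy model
  spec: lam(elevation) r(site)
  stations: 200   occasions (max): 8
  logLik: -712.778   AIC: 1433.556   k: 4   K: 50   converged: True

  parameter                       estimate          SE         z
  lam:(Intercept)                   0.0188      0.1212      0.15
  lam:elevation                    -0.6157      0.0717     -8.58
  r:(Intercept)                    -1.3852      0.1548     -8.95
  r:site[site02]                    0.1863      0.1753      1.06
```

The abundance intercept and slope recover the simulating values (0 and
−0.6) within one standard error; the detection intercept −1.39 on the logit
scale corresponds to r ≈ 0.20 per individual per 5-day occasion, and the
site-02 offset is within one SE of the simulated +0.3.
`res.derived_parameters()` adds
per-station λ, ψ and p; `occumap.mb_bootstrap(res)` runs the GOF test.

The full pipeline — including model selection, GOF, and the predictive map
— runs from one command:

```sh
occumap run-all --out my_run --seed 1
```

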