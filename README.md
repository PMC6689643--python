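# mandmorph

Landmark-based morphometrics of the macaque mandible with Bayesian mixed
models.  The package asks a concrete biological question — does captivity
change mandible shape in Japanese macaques, and does that change resemble
sexual dimorphism (a "masculinized" mandible)? — and implements the full
analysis a morphometrician would run:

1. **Shape extraction** — generalized Procrustes analysis (partial
   superimposition, proper rotations only) of 28 3D landmarks with an
   object-symmetry decomposition into symmetric and asymmetric components;
   log centroid size as the size variable.
2. **Screening** — Smirnov–Grubbs outlier test on Procrustes distances to
   the mean shape, then re-superimposition of the retained specimens.
3. **Shape variables** — PCA of the symmetric components; the first *m*
   score columns (default 10) serve as shape responses, with a
   distance-correlation diagnostic for the reduction.
4. **Modelling** — Bayesian Gaussian mixed models, fitted by an exact
   conjugate Gibbs sampler: per response
   `y = α + Xβ + u_pop + ε`, `u_pop ~ N(0, τ²)`, `ε ~ N(0, σ²)`, flat
   priors on coefficients and half-Student-t(3, 2.5) priors on the scales;
   multivariate shape models fit PC1…PCm jointly.  Split-Rhat, WAIC (with
   paired standard errors for model differences) and Bayes R² are computed
   from the draws.
5. **Effect geometry** — angles and element-wise correlations between the
   posterior coefficient vectors of different predictors (does the
   captivity direction align with the sex direction?), and the shape score
   `s = yβᵀ(ββᵀ)^-1/2` projecting specimens onto an effect's direction.

The original specimen landmarks are not public, so the package ships a
first-class synthetic-data generator (`mandmorph.synthgen`) that emulates
the study's structure — a 23-population design with uneven sample sizes,
captivity confounded with a subset of populations, bilateral symmetry,
low-rank anisotropic shape covariance, allometry, and ecogeographic
covariates correlated with latitude — together with ground-truth manifests,
so every stage is validated against planted structure.  See
`docs/methods.md` for the model details and the generator's stated world.

## Worked example

```python
import numpy as np
from mandmorph import synthgen, superimpose, shape_space, blmm, effect_geometry

# a synthetic study: 23 populations, 177 specimens, planted effects
data = synthgen.generate(synthgen.GeneratorConfig(seed=1))

aligned = superimpose.gpa(data.configs)            # GPA + symmetry split
pca = shape_space.fit_pca(aligned.flat("symmetric", tangent=True))
scores, diag = shape_space.retain(pca, 10)
print(f"first 10 PCs: {diag['cumulative_variance_fraction']:.3f} of variance, "
      f"distance correlation {diag['distance_correlation']:.3f}")

table = data.metadata.assign(size=aligned.log_centroid_size)
for j in range(10):
    table[f"PC{j+1}"] = scores[:, j]

spec = blmm.ModelSpec(
    responses=[f"PC{j+1}" for j in range(10)],
    fixed_effects=["size", "sex", "age_class", "captivity"],
    chains=4, iterations=2000, burn_in=1000, seed=7,
)
draws = blmm.fit(table, spec)
summary = blmm.summarize(draws)
cap = summary.table.query("parameter == 'captivity'")
print(cap[["response", "mean", "lower", "upper"]].round(2).head(4).to_string(index=False))

sex = effect_geometry.effect_vector(draws, "sex")
capv = effect_geometry.effect_vector(draws, "captivity")
res = effect_geometry.compare_effects(sex, capv, mode="within")
print(f"sex vs captivity: {res['angle_mean']:.0f} deg "
      f"[{res['angle_lower']:.0f}, {res['angle_upper']:.0f}], "
      f"independent: {res['angle_independent']}")
```

Output (seed 1):

```
first 10 PCs: 0.830 of variance, distance correlation 0.985
response  mean  lower  upper
     PC1  0.04  -0.16   0.24
     PC2  0.14  -0.06   0.33
     PC3 -0.24  -0.44  -0.04
     PC4 -0.28  -0.46  -0.08
sex vs captivity: 77 deg [52, 102], independent: True
```

Reading it: the retained scores summarize shape faithfully (score-space
distances correlate 0.985 with Procrustes distances); captivity shifts a
couple of shape axes by ≈ −0.25 sd with credible intervals excluding zero
(the planted 0.4 effect, attenuated by population confounding and spread
over the PCs its direction mixes into); and in this synthetic world the
captivity and sex directions are planted orthogonal, which the angle
interval (containing 90°) correctly reports.

## Command line

```sh
mandmorph simulate --seed 1 --outdir data/           # synthetic dataset
mandmorph screen data/landmarks.csv --alpha 0.05     # Grubbs report (JSON)
mandmorph run-all --config analysis.yaml             # full pipeline
```

`run-all` reads one YAML config (simulate block or landmark/metadata paths,
screening alpha, PC retention, model variants, subset filters, seeds) and
writes a report bundle: model summary tables, the WAIC comparison table,
effect-geometry intervals, shape scores and a run log — all deterministic
under a fixed seed.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch on the packaged-design synthetic
world at the full MCMC settings (4 chains × 10 000 iterations) — both the
captivity and the ecogeography analyses, each with full and reduced models
— and writes its report bundle beside the output file.  The package's
quantitative acceptance checks are property-based and live in
`tests/test_acceptance.py` (Procrustes and symmetry identities against
independent oracles, Grubbs operating characteristics, conjugate closed-form
and calibration checks for the sampler, planted-effect recovery, WAIC
discrimination, and byte-level determinism).
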