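# Methods

`mandmorph` re-implements, as a tested pipeline, a landmark-based analysis
of mandible shape and size differences between captive and wild Japanese
macaques: Procrustes shape extraction with an object-symmetry
decomposition, Bayesian multivariate mixed modelling of shape against
captivity, sex, age class, allometry and ecogeography with population
random effects, WAIC model comparison, and a vector geometry of effect
directions.  Because the original specimen landmarks are not public, the
package ships a synthetic-data generator with ground-truth manifests, and
all validation is against planted structure and independent oracles.

## Shape extraction

**Superimposition.** Partial generalized Procrustes analysis: every
configuration is centred and scaled to unit centroid size; only proper
rotations enter the fitting, iterated against the evolving consensus until
the root-mean-square consensus change falls below 1e-10 (at most 1000
iterations; random unrelated shapes converge slowly, real shape samples in
well under ten iterations).  Centroid size is the usual root summed squared
deviation from the landmark centroid; its natural log ("size") is the size
variable of all models.

**Object symmetry.** Each specimen contributes its original and its
reflected-and-relabelled copy (first axis negated, left/right labels
swapped) to the superimposition.  The symmetric component is the average of
the two aligned copies, the asymmetric component half their difference, so
`aligned = symmetric + asymmetric` holds exactly.  For the decomposition to
be exact the consensus must itself be reflection-invariant: after plain
convergence the consensus is rotated so that its symmetry plane coincides
with the first coordinate plane (the plane normal is recovered from the
symmetrized reflection operator; the left side is put at positive x), then
projected onto exact symmetry, and the superimposition is re-iterated
against this symmetric consensus.  Remaining orientation freedom — rotation
within the sagittal plane, and full principal-axis orientation when
symmetry is disabled — is fixed by principal axes with a
largest-element-positive sign rule, so runs are bit-reproducible.

**Tangent projection.** Aligned coordinates can be orthogonally projected
onto the tangent space at the consensus before PCA (`tangent=True`, the
default in the pipeline).  At the shape variation typical here the effect
is of order 1e-4 of the coordinates; it is switchable and documented rather
than load-bearing.

**Outlier screening.** A one-sided upper Smirnov–Grubbs test on the
Procrustes distances from the mean shape at alpha = 0.05, using the
Bonferroni-corrected Student-t critical value.  Distances to a mean are
non-negative, and only unusually large values signal aberrant specimens,
which motivates the one-sided choice (the sidedness convention is
switchable by changing alpha).  The default single pass mirrors a design in
which one outlier is removed before analysis; an iterative mode with a
re-superimposition hook is provided.  After removal the pipeline re-runs
the GPA on the retained specimens, so the analysed shape space never
contains the outlier.

**PCA.** Eigendecomposition (via SVD) of the flattened symmetric
components about their mean, loadings sign-fixed by the largest-absolute
element.  The retention default is 10 PCs — a configuration value, not a
constant — with a diagnostic correlating pairwise distances in the retained
score space against full-space Procrustes distances plus the cumulative
variance fraction.  `size_adjust` pools a per-coordinate regression on log
centroid size (R² = predicted over total sum of squares pooled over
coordinates; p by permuting the size vector, observed counted among the
permutations, default 9999) and returns residual shapes that can be fed
back into the PCA for the size-adjusted variant of the analysis.

## The mixed model

Per response r (a PC score, or log centroid size), with observations i in
populations g(i):

    y_ir = alpha_r + x_i' beta_r + u_{g(i),r} + e_ir,
    u_{g,r} ~ N(0, tau_r^2),   e_ir ~ N(0, sigma_r^2)

All responses and fixed-effect columns are z-scored first ("standardized"),
so coefficients are comparable across predictors and responses.  Priors:
improper flat on intercepts and coefficients; half-Student-t with 3 degrees
of freedom and scale 2.5 on tau and sigma.  The 2.5 matches what
weakly-informative defaults scale to for unit-sd responses.  Captivity
(0 wild / 1 founder / 2 captive-born) enters as a single numeric predictor,
matching a single reported captivity coefficient.

Multivariate (shape) models fit all responses jointly with independent
residuals across responses — PC scores are empirically uncorrelated by
construction — each response keeping its own coefficients, random
intercepts and scales.  The pointwise log-likelihood sums over responses,
so WAIC compares whole multivariate models.

**Sampler.** Gibbs, with exact conjugate updates throughout: coefficients
and group levels have Gaussian full conditionals; the half-t scales use the
inverse-gamma parameter expansion (a half-t(nu, A) scale is an
inverse-gamma mixture), giving inverse-gamma conditionals for tau², sigma²
and their auxiliaries.  All updates are vectorized across responses.
Defaults are 4 chains × 10 000 iterations with 5 000 burn-in (20 000
retained draws); tests use reduced settings (4 × 1500/500).  `sigma_fixed`
pins the residual scale, exposing the conjugate special case in which the
coefficient posterior is exactly N(b_ols, sigma² (W'W)⁻¹) — the sampler's
primary correctness oracle.  Split-Rhat (classic split-chain potential
scale reduction; verified against arviz's `method="split"`) above 1.1
raises a warning recorded in the fit summary, not an abort.

**Criteria.** WAIC on the deviance scale: lppd_i − p_i with
p_i = var over draws of the pointwise log-likelihood; the standard error is
sqrt(n) times the sd of pointwise contributions, and model differences use
the paired pointwise standard error.  Bayes R² is the per-draw ratio
var(fitted)/(var(fitted)+sigma²), averaged over responses for multivariate
fits.  Marginal effects fix other predictors at their means (zero on the
standardized scale) and random effects at zero.

## Effect geometry and shape score

Each fixed effect of the shape model yields, per posterior draw, a
coefficient vector over the shape variables.  Two effects are compared by
the angle between their vectors and by the plain Pearson correlation of the
vector elements (not the centred cosine), per draw.  Within one model,
draw t of one effect pairs with draw t of the other; between models, each
model's draws are compared against the other model's posterior-mean vector
and the two sets concatenated.  Independence is read off the 95% interval:
containing 90° (angle) or 0 (correlation).  The shape score is
s = y β'(β β')^(-1/2) — the scalar projection of the shape variables onto
β — computed with the posterior-mean coefficient vector on the
standardized scale (the scale the model was fitted on); it is invariant to
positive rescaling of β.

## Synthetic data: the stated world

The generator deforms an exactly symmetric mandible-like template (28
landmarks, packaged, synthetic) and writes the package's own file formats
plus a ground-truth manifest.  Default design: the packaged 23-population
sampling table (uneven sizes 1–32, captive populations distinct from wild
ones, 101 females / 76 males, 25 young adults — 177 specimens), with
population-level temperature and precipitation generated from latitude with
noise so that |r(latitude, climate)| ≈ 0.7–0.8.  A uniform design
(`n_populations` × `n_per_population`) serves scaled-down simulation
studies.

Real shape covariance is strongly anisotropic — a few PCs carry most
variance — so individual "biological" variation is low-rank: independent
normal deviations along 10 fixed orthonormal symmetric deformation
directions (orthogonal to the similarity-transform subspace at the
template) with geometrically decaying scales 2.5 → 0.8 mm, on top of 0.3 mm
isotropic symmetric digitizing noise and 0.3 mm asymmetric noise.  The
first five latent directions are the effect directions (allometry, sex,
age, captivity, temperature); an effect of size e displaces shape along its
direction by e times that direction's latent sd per covariate sd.  With the
default sizes (sex→size 0.7, age→size 0.2, allometry 0.5, sex→shape 0.5,
age→shape 0.2, captivity→shape 0.4) the generated world reproduces the
diagnostics reported for the real data — first 10 PCs ≈ 82% of total
variance, score-space distance correlation ≈ 0.985 — without further
tuning.  Size is log-normal: planted sex/age effects, population intercepts
(sd 0.03) and residual noise (sd 0.05) on the log scale; coordinates are
scaled to the realized centroid size and, with nuisance on, randomly
rotated and translated.

Effects are planted in landmark-coordinate space because PCs are
data-dependent; `truth_in_pc_space` maps the planted coefficients into a
fitted PCA's frame (rotation from the unit template onto the consensus,
scale by 1/template size, projection through the retained loadings,
standardization with the realized covariate and score sds) so recovery is
testable on the model's own scale.  What a green recovery test does *not*
establish: realism of mandible biomechanics, growth, measurement error
structure, or inter-population genetic covariance — the generator emulates
the statistical assumptions of the analysis, nothing more.

## Numerical and testing choices

- GPA convergence 1e-10 RMS consensus change; symmetrization applied to the
  consensus each iteration of the second phase; degenerate (rank < 2)
  configurations are errors.
- PCA drops components below 1e-12 of total variance; all decompositions
  are deterministic with fixed sign rules.
- Landmark CSV I/O writes shortest-round-trip decimal representations and
  parses with correctly rounded floats, so read(write(x)) is bit-exact.
- A single-replicate angle between an estimated coefficient vector and a
  planted direction has expectation ≈ atan(sqrt((m−1)/n)/‖β‖) even for an
  unbiased estimator (≈ 15–20° at n = 240, m = 4, ‖β‖ ≈ 0.35), so direction
  recovery is assessed on the estimate pooled over independent replicates;
  per-replicate coefficient magnitudes are checked individually.
- WAIC model discrimination for a 0.4-sd planted effect needs n ≈ 240 per
  replicate (the expected ΔWAIC at n = 96 is ≈ 2, within noise); simulation
  studies are sized accordingly.

## Known limitations

- Residual correlations between shape responses are not estimated (PCs are
  uncorrelated marginally, but conditional correlations could exist);
  the independence assumption is the default and the only mode exercised.
- Wild specimens have no ages, so the age filter applies to captives only.
- The asymmetric component is computed but unused downstream.
- No 3D rendering; wireframe endpoints are emitted as coordinates.
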