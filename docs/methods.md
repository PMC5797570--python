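# Methods

## Scientific setting

Topsoil element concentrations (mg/kg) are *compositional*: each sample's
parts are tied to an (approximately) constant total, so correlations among
raw or log concentrations are distorted by closure.  Geochemical signal is
also collinear — elements co-occur in ore bodies and parent lithology — so
epidemiological interest attaches to a few latent element *associations*
rather than to single elements.  Mortality, meanwhile, is aggregated at
town level while soil is sampled at points: the exposure for a town must be
interpolated, and ignoring the interpolation error ("naïve" plug-in
kriging) biases effect estimates towards the null and understates their
uncertainty.  The package implements the full chain: open the composition,
factor it, and fit a joint Bayesian model in which the exposure surface and
the mortality risk are estimated together.

## Compositional transforms

Two openings of the data are provided.

* **Standardised log**: per element, `y = (log x − mean(log x)) / sd(log x)`
  with the sample (n−1) standard deviation.  The sd convention is ours; the
  choice only rescales columns and is immaterial downstream because factor
  analysis runs on the correlation matrix.
* **Centred logratio (clr)**: per sample, `y_i = log(x_i / g(x))` with
  `g` the geometric mean of that sample's D parts, computed as
  `exp(mean(log x))` to avoid overflow of D-fold products.  clr rows sum to
  zero, so the clr correlation matrix is singular (rank ≤ D−1); every
  downstream step uses pseudo-inverses so this case is first-class.

Zeros are rejected, not imputed: the transforms are undefined at zero and a
detection-limit policy would be a modelling decision we do not take
silently.

## Principal factor analysis

Extraction is iterated principal-axis factoring on the correlation matrix:
squared multiple correlations (via pseudo-inverse) start the
communalities, the reduced matrix (communalities on the diagonal) is
eigendecomposed, loadings are the top-k eigenvectors scaled by the square
roots of the (non-negative-clipped) eigenvalues, and communalities are
iterated to a fixed point (tolerance 1e-6, cap 200 iterations; exceeding
the cap raises).  Heywood cases are clamped to communality 1 and flagged.

The factor count is the smallest k whose cumulative explained-variance
fraction exceeds a threshold (default 0.75).  Fractions are eigenvalue
shares of the SMC-reduced matrix relative to the total observed variance D;
with common-factor extraction the fractions sum to less than one, so the
rule can be unsatisfiable on weak-structure data — that is reported as an
error rather than silently relaxed.

Rotation is varimax with Kaiser row-normalisation (delegated to
statsmodels' factor-rotation routines behind our surface; a brute-force
rotation-angle search is the independent oracle in the tests).  After
rotation, any factor whose largest-|loading| element is negative is
flipped, with exact ties resolved to the first tied element — the sign of
a factor is arbitrary and the flip makes the dominant elements load
positively.  Factors are then ordered by explained variance.  Factor
labels list the signed elements with |loading| ≥ 0.4.

Scores use the regression (Thomson) estimator `c = z R⁺ L` on
column-standardised data, which is well-defined under the clr singularity
and gives exactly mean-zero scores.  Explained-variance fractions are
reported both pre- and post-rotation, since rotation redistributes
variance across factors.

## Spatial machinery

**Mesh.**  Without a constrained-triangulation library we build a
structured mesh: a hexagonal lattice at spacing 0.95 × `max_edge` covering
the bounding box of all data locations (so no interior Delaunay edge
exceeds `max_edge`, with the 0.05 margin absorbing boundary
irregularities), surrounded by a coarser lattice ring (spacing scaled by
`extension_factor`, width defaulting to max(15% of the domain diameter,
two coarse edges)) that pushes the boundary of the PDE domain away from
the study region; the union is Delaunay-triangulated.  Points on shared
edges are assigned to the lowest-index containing triangle for
determinism.

**SPDE field.**  The Matérn field uses smoothness ν = 1 (the standard
choice of the finite-element SPDE construction in 2-D, where α = 2), the
practical-range parameterisation κ = √8/ρ (correlation ≈ 0.14 at distance
ρ), and precision `Q = τ²(κ⁴C + 2κ²G + GC⁻¹G)` with lumped (diagonal) mass
matrix C and stiffness matrix G; τ is set from (κ, σ) so the stationary
marginal sd is σ.  On a fine mesh the implied correlations match the
closed form `(κd)K₁(κd)` to within 0.05 at mid-range distances; the lumped
mass matrix inflates marginal variance by a few percent at practical
resolutions, within the 10% band we test.

**Town structure.**  The BYM decomposition uses the intrinsic CAR
structure matrix `Q_u = D − W` over the town adjacency graph plus an iid
normal term.  For exact simulation the intrinsic prior is sampled in its
positive-eigenvalue subspace with per-component sum-to-zero constraints.
Inside the fitting algorithm the intrinsic precision is made proper by a
small ridge (0.01·I): the per-component flat direction is then only weakly
penalised, and the intercept's proper prior keeps the overall level
identified.  This avoids densifying the sparse precision with explicit
constraint blocks.

## The joint model and its estimation

Per town, `O_i ~ Poisson(E_i λ_i)` with
`log λ_i = α + β·expos_i [+ Σ δ_j Soc_ij] + u_i + v_i`; per soil sample,
`c_j ~ Normal(x(s_j), σ_x²)`; `expos_i = x(s_i)` is the same latent field
at the town centroid.  The score model uses an **identity link**, not a
log link: varimax factor scores are signed, mean-zero quantities, and a
log link is undefined on them.  RR = exp(β) is the relative risk per unit
of factor score.

Priors: α, β, δ ~ N(0, 10²); half-normal(1) on σ_x, σ_f, sd_u, sd_v;
log-normal on ρ centred at one third of the domain diameter with unit log
sd.  The population-size category enters as two dummies against the rural
baseline.  Each factor is fitted in its own one-dimensional exposure
model; no multiplicity adjustment is applied across an endpoint battery —
the `excludes_one` flag is a per-fit statement.

**Inference** is a nested Laplace scheme exploiting the sparse precision.
β multiplies the latent field, so it is carried as a hyperparameter
(alongside σ_x, ρ, σ_f, sd_u, sd_v), keeping the latent vector
z = (x, u, v, α, δ) conditionally Gaussian.  For each hyperparameter value
the mode and curvature of z|θ come from Newton iterations with sparse LU
factorisations (warm-started across evaluations; step halving; the linear
predictor is clipped at ±30 against overflow).  The Laplace-approximated
log evidence is maximised by Nelder–Mead (evaluation budget
`inference.iterations`, default 400), initialised from an exposure-only
marginal fit plus a plug-in Poisson IRLS slope.  The hyperparameter
posterior is summarised by a Gaussian approximation from the numerical
Hessian at the optimum (central differences; steps 0.02 for β, 0.08 for
log-scale parameters); scale parameters are reported by exponentiating the
normal approximation on the log scale, so quantile ordering holds by
construction.  α and δ take their conditional posterior sd at the
hyperparameter optimum, which slightly understates their marginal
uncertainty; β — the parameter of interest — carries the full
hyperparameter-level uncertainty.  Everything is deterministic given the
seed; the `converged` flag requires optimiser termination within budget
and a positive-definite Hessian.

**Naïve comparator.**  Stage 1 fits the Gaussian exposure layer alone by
maximising the exact GMRF marginal posterior over (σ_x, ρ, σ_f) and
kriges the field to the centroids; stage 2 fits the Poisson/BYM layer with
the kriging mean as a fixed covariate (β is then linear, and its posterior
is conditional on the stage-2 hyperparameter optimum).  The comparator
deliberately ignores the kriging error — that is the point being
demonstrated.

## Synthetic scenarios

The generator draws k* independent Matérn fields on a scenario mesh,
builds log concentrations as `base + L* f(s) + noise` (exponentiated,
hence positive; optionally closed to a constant row total to reproduce the
closure artefact), places towns on an r × c lattice with queen adjacency,
classifies lognormal populations into rural / semi-urban / urban strata,
scales expected counts to a configurable mean, and draws Poisson deaths
from the same log-linear model the estimator fits, with the *latent field
value at the centroid* as the exposure — so the measurement-error
structure is reproduced exactly.  A confounding knob correlates the first
covariate with the exposure field.

Reference conditions: a 20 km square, 20 × 20 towns, 600 samples, D = 6
elements with two planted factors, field range = side/4 and unit sd,
score measurement sd 0.3, log-concentration noise sd 0.3, β = (0.2, 0),
BYM sds (0.1, 0.05), mean expected count 30.  Element bases are typical
topsoil geometric means.  The mean expected count of 30 reflects a decade
of common-tumour mortality in mid-sized municipalities and gives the
Poisson layer realistic information content.

What the generator does *not* emulate: irregular town polygons and
coastline-shaped domains, age–sex structure inside expected counts
(standardisation is upstream of the model), multi-tumour correlation,
spatially clustered sampling designs, and real geochemical abundance
patterns.  Passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to their
violation.

## Problem sizes and numerical tolerances

Test and acceptance runs use scaled scenarios chosen to exercise every
code path at desk scale: reference fits on 400 towns / 600 samples, and
replicated comparisons (attenuation, null calibration, confounding) on
8 × 8 town lattices with 80–100 samples and an evaluation budget of 250.
Compositional identities are asserted at 1e-10–1e-12; varimax against the
brute-force angle search at 1e-6; SPDE-vs-closed-form correlation at 0.05
on a fine mesh; effect recovery at the generator's own Monte-Carlo spread.

## Known limitations

* The Gaussian approximation over hyperparameters ignores posterior skew;
  intervals for the field hyperparameters are approximate (β, which is
  nearly Gaussian a posteriori in these regimes, is well served).
* The intrinsic-CAR ridge is a pragmatic proper-ification; a sum-to-zero
  constrained solver would be exact.
* One factor per outcome model, by design; joint multi-factor exposure
  models are out of scope.
* The mesh builder assumes a roughly convex study region; concave
  coastline-following boundaries are not traced.
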