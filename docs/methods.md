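# Methods

This note records the models, algorithms, defaults and numerical choices
behind `effparam`, and what the built-in synthetic studies do and do not
demonstrate.

## Kinetic testbeds

**Dual phosphorylation (six rates).**  Mass action for
E + S0 ⇌ ES0 → ES1 (⇌ E + S1) → E + S2 gives six ODEs; enzyme
(E + ES0 + ES1) and substrate (S0 + S1 + S2 + ES0 + ES1) totals are
conserved exactly by the right-hand side, and to ≤1e-6 relative along
solved trajectories.  The nominal operating point is
p̃ = (kf1, kr1, kcat1, kf2, kr2, kcat2) = (0.71, 19, 6700, 0.97, 9200, 5200)
with reference initial condition [S0]=5, [E]=0.66 and output [S2] at
t ∈ {2, 4, …, 20} (time in the solver's own unit; no conversion).  The
widely circulated printed form of this vector lists 9200 before 0.97 with
labels that would assign kf2=9200, kr2=0.97; only the swapped assignment
reproduces the accompanying effective-parameter values
(kappa1, kappa2, pi) ≈ (0.467, 0.231, 0.361), so the swapped assignment is
the default and the literal one is available via
`MSPParameters.from_printed_vector(..., assignment="printed")`.  Direct
evaluation gives kappa2 = 0.2312 and pi = 0.3611 versus the commonly quoted
0.232/0.362 — a ≤0.5 % rounding-level discrepancy we simply report.

**Solver.**  LSODA with the analytic 6×6 Jacobian, rtol 1e-8 / atol 1e-10
(the rates span five orders of magnitude, so the problem is stiff; the
implicit branch of LSODA with an exact Jacobian integrates the reference
transient in ~3 ms).  Solver-level negative round-off is clipped at output.

**QSSA reduction.**  The three-state linear model
S0' = −kappa1·S0, S1' = (1−pi)·kappa1·S0 − kappa2·S1,
S2' = pi·kappa1·S0 + kappa2·S1 is solved in closed form (two exponentials;
the confluent case kappa1 ≈ kappa2 switches to the t·exp limit at relative
gap 1e-9); tests verify it against a `scipy` matrix-exponential oracle to
1e-10.  The QSSA validity ratios are S_tot/K_i with
K_i = (kr_i + kcat_i)/kf_i (Michaelis-type constants; a variant with
(kf1 + kcat1)/kf1 circulates and is provided behind `as_printed=True`, but
is dimensionally inconsistent for a binding step), with flag threshold 0.1.
At p̃ both ratios are ≈0.04/0.003, and the full-model [S2](t) tracks the
reduced model within 0.07 % on the observation window (test bound frozen
at 2 %).

**Single-site caricature (three rates).**  S0 + E ⇌ ES0 → S1 + E with
reference initial condition (5.0, 0.66, 0, 0), output [S1] every 2 time
units for five points, and effective rate
k_eff = E_tot·kf·kcat/(kr + kcat).  Base points (0.71, 19, 6700)
(k_eff ≈ E_tot·kf) and (0.97, 7000, 10000) (all three rates matter to
k_eff) are built in.

## Synthetic ensembles

Every study dataset is generated, never stored: uniform box perturbation of
each rate within ±10 % (dual phosphorylation) or ±20 % (caricature,
effective-parameter triplets) of its base value, with `default_rng` seeds
recorded in the dataset metadata.  Default sizes: 3000 transients for the
dimension count (the published analysis used 10⁴; 3000 reproduces the count
and keeps a full pipeline run in seconds-to-minutes on one core), 5000
triplets for interpolation studies, 2000 caricature samples, 500 refit
starts.  These ensembles emulate *noise-free, densely sampled* perturbation
experiments around a single operating point.  They do not emulate
measurement noise, sparse or irregular sampling, model misspecification, or
operating-point drift — so passing tests demonstrate the machinery, not
robustness to laboratory data pathologies.  (The kernel methods tolerate
output noise up to roughly the kernel scale; that regime is not exercised
here.)

**Refit ("equivalent optima") ensemble.**  All six rates are refit to the
reference transient by trust-region-reflective least squares in
log10-parameter space (positivity for free), objective = the ten [S2]
residuals, starts drawn log10-uniformly within 10^±3 of the base rates,
bounds the same (the original experiment centered bounds on literature rate
estimates that are not reproduced here; centering on the base point is the
documented substitute).  During the search the ODE tolerance is relaxed to
rtol 1e-6; candidate optima are re-simulated at full accuracy and accepted
when the relative residual ‖r‖/‖ref‖ ≤ 1e-4, so acceptance is a statement
about the accurate model.  With 500 starts, ~47 % converge (the rest stall
in shallow side valleys at residuals of a few 1e-4).  Accepted fits wander
across decades along the level set while reproducing the reference to
1e-4 — the concrete face of nonidentifiability.

## Diffusion maps and the dimension count

Standard construction: Gaussian kernel W = exp(−d²/ε) on behavior vectors
(Euclidean metric on the raw output vectors — "output-informed"),
density normalization with α = 1, row-normalized Markov operator
diagonalized through its symmetric conjugate; eigenvectors scaled so the
trivial one is the constant 1, signs fixed deterministically.

**Kernel scale.**  The `median` rule (median squared pairwise distance) and
a log-log kernel-sum `plateau` rule are both provided.  For *dimension
counting* the default scale is 20× the median rule.  This wide-kernel
regime is deliberate: the model manifolds here are strongly anisotropic
(principal-extent ratios ≈ 1 : 0.17 : 0.016 for the dual-phosphorylation
transient ensemble), and for a near-Gaussian cloud the kernel eigenfunctions
approach Hermite polynomials of the principal axes, whose eigenvalue
ordering at wide scales ranks the *first-order mode of each thin axis* ahead
of high-order harmonics of the dominant axis.  A small eigenpair budget
(m = 25) then contains one eigenvector per independent direction; at
median-rule scales the thinnest direction would appear only thousands of
eigenvectors deep.  The count is verified stable across a ×10 sweep of ε in
the tests.

**Parsimonious (nonharmonic) selection.**  Each eigenvector is regressed on
the retained coordinates by Gaussian-weighted local linear regression with
the evaluation point left out; the normalized residual is minimized over a
bandwidth sweep (median predictor distance divided by 1.5, 3, 6, 12) —
a harmonic becomes predictable once the bandwidth resolves its wavelength,
a new direction never does.  Candidates with residual > 0.5 open a new
direction **if** they are also smooth over the ambient data (leave-one-out
residual against the behavior vectors < 0.15).  The smoothness filter is the
resolution cut of the method: eigenvectors oscillating inside directions
thinner than the sampled density can resolve (e.g. the caricature
ensemble's sub-percent QSSA-violation directions) fail it and are not
counted, while genuine coordinates score ≤0.07.  Two design traps motivated
this form and are worth recording: regressing on *all* previous eigenvectors
(instead of retained ones) lets a harmonic that carries a few percent of an
independent direction — eigenvector mixing is generic at close eigenvalues —
be inverted by the local regression into a spurious "prediction" of that
direction; and a single regression bandwidth either misses cross-harmonics
or flags sub-resolution directions.  Thresholds (0.5 / 0.15) were calibrated
on analytic oracles (a circle, which correctly needs two embedding
coordinates, and a 5:1 strip, which needs two with the second at a deep
index) and frozen before any acceptance run.

**Refit-ensemble dimension.**  The accepted-fit set is a level set
*thickened* by the 1e-4 acceptance slack and heavy-tailed across decades;
kernel counting on it is scale-sensitive, while its raw-coordinate PCA
spectrum is robustly rank-3 (cumulative explained variance
0.85 / 0.98 / 0.9995).  The end-to-end study therefore reports the refit
dimension as the number of principal components reaching 99.9 % variance
(accepted fits reproduce the reference to 1e-4, so genuine level-set
directions each carry far more than the remaining 0.1 %), and
keeps kernel counting available as an API mode.

## Geometric harmonics and Double DMaps

Plain geometric harmonics: eigendecomposition of the Gaussian kernel on the
training inputs, retain eigenpairs with σ ≥ δ·σ₀ (default δ = 1e-6; the
extension amplifies by at most 1/δ), project the target on the retained
span, evaluate out of sample through the kernel columns.  The default
extension scale is 4× the median rule — wider than a diffusion-map kernel,
because the basis must reach between and slightly beyond samples rather
than resolve fine structure.

Double DMaps interpolate functions *of the manifold coordinates*: a second
diffusion map is fitted on the retained coordinates of the first, its
eigenvectors (orthogonal under its stationary measure) serve as the basis
(m2 = 300 computed, eigenvalue cutoff 1e-8 relative), and evaluation at a
new ambient point composes the first map's Nystrom extension with the
second map's.  Directed maps built this way:

- behavior prediction (triplet → transient): max held-out relative error
  ~2e-5 % on the ±20 % triplet box — far inside the 0.1 % working
  tolerance;
- effective-parameter estimation (transient → triplet): max 0.07 % on the
  dual-phosphorylation ensemble.  On the synthetic ±20 % triplet box the
  *inverse* direction is ill-conditioned along the manifold's thin
  direction (aspect ~1:60 between the leading and thinnest behavior
  responses), which amplifies interpolation error ~60×: bulk recovery is
  ~0.2 % (median) with a few-percent tail at the box boundary.  This is a
  property of the inverse problem, not of the interpolant; the behavior-side
  round trip predict(estimate(·)) still closes to 0.6 %.

Invertibility of the coordinate → effective-parameter map is checked by
central finite differences (step 1e-4 of each coordinate's range): the
determinant of the 3×3 Jacobian stays bounded away from zero over all
training points (min ≥ 5 % of the median magnitude in tests).

Behaviors far from the sampled manifold (minimum squared distance beyond 3
kernel scales) raise an out-of-manifold error rather than silently
extrapolating; queries outside the sampled parameter box warn.

## Neural-network stack

`effparam.nn` is a self-contained reverse-mode autodiff engine on numpy
arrays with exactly the primitives the package's architectures need, plus
Adam and an `MLPRegressor` (standardized inputs, raw-scale targets, step
learning-rate decay at 60 %/85 % of the epochs, early stopping on a
validation split).  The input-Jacobian of a network is propagated layer by
layer with engine primitives (Jᵢ₊₁ = diag(1−a²)·Wᵀ·Jᵢ), making it an
ordinary graph node: one reverse sweep differentiates Jacobian-dependent
losses, no second-order machinery.  Gradients are verified against finite
differences to ~1e-9 in the tests.  The alternative realization of the
coordinate ↔ effective-parameter maps is a five-hidden-layer, 30-unit tanh
network trained with Adam (lr 2e-3, batch 256); it reaches test MSE ≤1e-6
in raw effective-parameter units within 800 epochs for at least one of
three initializations.

## Conformal autoencoder

Architecture: encoder P → P, decoder P → P, behavior estimator
n_eff → D, each 4×32 tanh (an optional behavior → effective-latent
estimator subnetwork exists but is off by default — the Double-DMaps route
serves that direction).  The latent dimension equals the input dimension;
the first n_eff coordinates are the effective block and n_eff must be
supplied from the diffusion-map dimension count.  The behavior estimator
receives *only* the effective block, so redundant coordinates cannot
influence predicted behavior by construction.

Loss = reconstruction MSE + behavior MSE + conformality penalty, equally
weighted, on standardized inputs and outputs.  The penalty is the mean
*squared cosine* between pairs of latent input-gradients: normalizing by
the gradient norms matters, because the raw inner-product penalty lets
low-gradient regions hide residual non-orthogonality (observed: score 0.09
with raw dots vs 0.002 with cosines on the analytic toy, at identical
budgets).  Training: Adam lr 1e-3, batch 64, 600–2000 epochs with step decay
and validation early stopping; seeds control initialization and batching
and are recorded in the training report together with the final value of
every loss term.

Level sets are traced by decoding a grid over the redundant block at fixed
effective coordinates (default: the interior 50 % of the observed latent
range — the decoder warns when asked to extrapolate beyond it); quality is
reported as the maximum relative deviation of the simulated behaviors from
the grid center against the relative spread of the decoded parameters.
Measured on the caricature: behavior moves ≤0.05 % while rates move
19–35 %.

## Jointly smooth functions

Per dataset, a d-dimensional orthonormal Gaussian-kernel eigenbasis
(d = 64 default, median-rule scales); SVD of the concatenation [U1 U2];
singular values in [0, √2] score joint smoothness, with retention at
≥ 0.9·√2.  The shared constant function always scores √2 and is excluded
from "first JSF" statements by a variance test.  Redundant combinations:
the X2 eigenbasis, weighted by its kernel eigenvalues so smooth functions
carry more norm, is projected orthogonal to the retained JSFs and
re-orthonormalized; the weighting is what makes the leading redundant
functions the *smoothest* parameter functions the output cannot see
(unweighted, the complement is led by arbitrary high-frequency modes).
On the noise-substituted caricature pair the first nonconstant JSF tracks
k_eff at |Spearman| ≈ 0.996; on the clean pair the leading jointly smooth
block is ~3-fold degenerate (80 clean delayed measurements resolve more
than k_eff), so robustness to the noise substitution is asserted on the
spanned subspace, not on individual singular vectors.

## Known limitations

- All claims are local to the sampled neighborhood of the base point; the
  level-set patches and the latent disentanglement are a starting point for
  wider exploration, not global statements.
- The dimension count inherits a resolution: directions thinner than the
  ambient-smoothness filter can resolve at the sampled density are not
  counted.  That is the desired behavior for approximate reductions (the
  caricature is "1-D" only because its QSSA-violating thickness is
  sub-resolution) but it means the count can change under drastically
  denser sampling.
- Behavior → parameter estimation degrades near the sampled boundary and
  along near-degenerate output directions (quantified above).
- Kernel stages build dense n×n matrices; ensembles beyond ~10⁴ points
  need out-of-core or sparse variants that are out of scope here.
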