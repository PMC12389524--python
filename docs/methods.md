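# Methods

## The model

The core estimator is ε-insensitive support vector regression solved in its
kernelized dual: minimize ½‖w‖² + C Σ(ξᵢ + ξᵢ*) subject to the ε-tube
constraints, giving the predictor f(x) = Σⱼ (αⱼ − αⱼ*) K(xⱼ, x) + b. The
kernel is the convex combination

K_MIX = α·K_trig + β·K_poly + (1 − α − β)·K_linear,
  K_trig(x, y) = sin(π/2 + σ‖x − y‖²),
  K_poly(x, y) = (γ xᵀy + r)^d,

with α, β ∈ [0, 1], α + β ≤ 1. The trigonometric kernel has unit diagonal
and high learning capacity but is **not positive semidefinite** in general;
the polynomial and linear parts are PSD and contribute generalization. The
written-out distance term is read as the squared Euclidean norm, which gives
the kernel a unit diagonal and makes σ an inverse-squared-length-scale.

### Handling indefiniteness

The mixed Gram matrix can have substantial negative spectral mass once
σ times the typical squared inter-point distance exceeds ~1. Three standard
remedies were evaluated on synthetic nonlinear data before one was fixed:

- *eigenvalue clipping* (project the training Gram to the PSD cone, predict
  with the original kernel) leaves a residual term (K_orig − K_clip)·a in
  every prediction that scales with C and the clipped mass; empirically it
  destroys generalization entirely (test R² of −10²…−10⁶).
- *diagonal shift* (add |λ_min|·I) fails the same way once |λ_min| is
  comparable to the signal eigenvalues, because the fitted duals absorb the
  shift.
- *spectrum flip* (Krein-space stabilization): solve the convex QP on
  K_flip = V·|Λ|·Vᵀ, then transform the solver's duals ã to prediction
  coefficients a = V·sign(Λ)·Vᵀ·ã. Then K_orig·a = K_flip·ã *exactly* —
  training predictions with the original kernel coincide with the solver's
  fitted values — and test predictions extend with the original kernel.

The package uses the flip. For PSD kernels the transform is the identity and
ordinary SVR is recovered; the flipped (negative) spectral mass is recorded
on every fitted model. The solver's dual vector retains the usual box and
equality constraints (|a| ≤ C, Σa = 0); the transformed prediction
coefficients need not, and both are stored. The dual QP itself is dispatched
to libsvm via scikit-learn's `SVR(kernel="precomputed")`; an iteration-budget
overrun raises an explicit convergence error rather than returning a stale
solution.

Descriptors are z-scored by training means and standard deviations before
any kernel evaluation (constant columns get unit scale), and identically at
prediction time. Without a fixed input scale, σ and γ are meaningless.

## Hyperparameter search (CLPSO)

Comprehensive-learning PSO updates each velocity dimension toward the
personal best of a possibly different particle (its exemplar):
V ← ωV + c·rand·(pbest_exemplar − X). Exemplars are drawn per dimension with
learning probability Pcᵢ (the better of two randomly drawn other particles'
pbests, else the particle's own), with one dimension forced foreign if all
self-assigned, and are refreshed only after a particle has stagnated for
`refreshing_gap` steps. Constants follow the original CLPSO literature and
are all configurable:

| parameter | default | meaning |
|---|---|---|
| Pcᵢ | 0.05 + 0.45·(e^{10(i−1)/(ps−1)}−1)/(e^{10}−1) | per-particle learning probability, ramps 0.05 → 0.5 |
| refreshing gap | 7 | stagnation steps before exemplar refresh |
| c | 1.49445 | acceleration constant |
| ω | 0.9 → 0.4, linear in evaluations | inertia |
| V_max | 0.2 × search range per dimension | velocity clamp |

Positions are clamped to bounds with the velocity zeroed in clamped
dimensions. Integer dimensions keep continuous positions, rounded only when
a fitness is evaluated and in the reported best. Dimensions flagged
log-scale (SVR cost, ε, σ, γ) are searched in log10 coordinates, the usual
parametrization when plausible values span decades. The plain-PSO update
(V ← ωV + c₁r₁(pbest−X) + c₂r₂(gbest−X)) is provided as a baseline; on
multimodal test functions CLPSO's diversity preservation wins once the
budget allows convergence (5-D Rastrigin, 8000 evaluations: median 0.0 vs
1.0 over 20 seeds), while on unimodal bowls canonical CLPSO is deliberately
slower — a 5-D quadratic needs roughly 1500 evaluations to reach 1e−2, and
small swarms (4–10 particles) are used for low-dimensional problems so a
fixed budget buys more iterations.

The `cv_fitness` adapter maps a hyperparameter position to pooled k-fold
cross-validation loss (RMSE or 1 − Q²) with a partition fixed once per
adapter (seeded shuffle, contiguous blocks), making the fitness
deterministic in the position; evaluations are cached keyed by the rounded
position. Infeasible mixture weights (α + β > 1) are repaired by scaling
onto the simplex face and the repair logged; evaluations that fail
(solver non-convergence, numerical errors) are penalized with +∞ rather
than aborting the search.

## Tree ensembles and descriptor selection

Regression trees are exact greedy CART under squared error: candidate
thresholds are midpoints between consecutive sorted unique values, the split
maximizing the SSE decrease τ² = SSE_parent − SSE_children is taken, and
ties are broken by (feature index, threshold) lexicographic order, so fits
are fully deterministic. A split must improve SSE by more than a 1e−12
relative guard. Gradient boosting starts from the training mean and fits
each stage to the current residuals with a constant learning rate; random
forests bootstrap rows with a seeded generator (optional per-tree feature
subsampling, all features by default) and average tree predictions.

Split-gain importance of a feature is the sum of τ² over that feature's
split nodes, averaged over the trees of the ensemble; shares normalize to
one, and ranking ties are broken by column index. Descriptor selection fits
a gradient-boosted ensemble on all descriptors (defaults: 60 stages,
learning rate 0.1, depth 3), ranks by importance, then walks the ranking
keeping a descriptor only if its |Pearson r| with every kept descriptor is
below 0.8, until k are kept. The number k is an explicit argument; the
importance report also exposes successive rank-ratio gaps so a caller can
apply an elbow heuristic instead.

## Linear path

The pre-filter drops, in order: constant columns; columns with
one-descriptor regression F < 1; for each pair with |r| > 0.8, the member
with the lower single-descriptor R²; and columns with one-descriptor |t|
below a user threshold (default 1.96). The filter is idempotent and logs
every removal with its rule and statistic. Forward selection greedily
maximizes R² at each size and reports leave-one-out R²cv computed by the
closed-form PRESS identity (residual / (1 − leverage)). The published
three-descriptor linear model is exposed as a direct evaluator; its exact
descriptor values are not reproducible here because the original
descriptor calculation chain (commercial software) and per-compound values
were never published.

## Validation statistics

R² is 1 − SSE/SST with SST centered on the observed values being scored —
this definition, not squared Pearson correlation, reproduces the published
mixed-SVR test statistics from the packaged per-compound table. RMSE uses
divisor n. Q²(LOO) refits n times with PRESS over the full-response mean;
Q²(k-fold) pools out-of-fold predictions from a seeded contiguous-block
partition and reduces exactly to LOO at k = n. CCC is Lin's concordance
with 1/n moments. QF1² and QF2² share the test-prediction SSE and differ in
centering the denominator on the training vs the test mean.
y-randomization permutes responses with a seeded generator, refits with
unchanged hyperparameters, and reports (R², Q²_LOO) per repeat. Default
acceptability thresholds: R² > 0.7, Q²LOO > 0.6, Q²5fold > 0.55,
CCC > 0.85, QF² > 0.7.

The applicability domain uses leverage hᵢ = xᵢᵀ(XᵀX)⁻¹xᵢ over the training
descriptor matrix with an intercept column, warning leverage h* = 3p/n with
p = descriptors + 1, and standardized residuals scaled by the
training-residual standard deviation (population sd). Classification:
|std. residual| > 3 → response outlier; h > h* otherwise → influential;
else in domain.

## Reference data

The packaged reference table transcribes the measured lg(IC50) of 92
inhibitors and the per-compound predictions of six published models, with
the published 73/19 train/test partition; it is checksummed at load.
Recomputing summary statistics from it reproduces the published values for
the mixed-kernel SVR column only (train R²/RMSE 0.9446/0.1658 vs printed
0.9445/0.1659; test 0.9489/0.1816 vs 0.9490/0.1814). The per-compound
predictions printed for the other five models are *not* numerically
consistent with their printed summaries (e.g. the linear model's test RMSE
recomputes to ≈0.27 against a printed 0.6215); `reproduce-table6` reports
these as mismatches, and no quantitative claim in this package relies on
those columns. The published CCC/QF² values for the mixed model also do not
recompute from the 19 printed test rows (the evaluation set used for them
is unreported), so they are not asserted anywhere.

## Synthetic data

The generator emulates the statistical structure QSAR descriptor tables
present to a selection/fitting pipeline, not the marginal distributions of
real computed descriptors. Informative descriptors are i.i.d. standard
normal; redundant descriptors are ρ·parent + √(1−ρ²)·noise with ρ > 0.8 in
expectation (default 0.95), so they must fall to the correlation filter;
noise descriptors are independent. The linear response is a fixed
coefficient combination; the nonlinear response is
f(x) = Σₖ wₖ·cos(s·‖x_inf − cₖ‖²) over 5 random anchors — a target inside
the trigonometric kernel's hypothesis class. The distance scale s defaults
to 0.3, making the surface vary over roughly one cosine period across the
typical inter-point distance range: smooth but genuinely nonlinear, and
learnable in the near-stable σ regime. Response noise is Gaussian with
configurable sd in lg units (default 0.1). Ground truth is returned
separately from the table so tests never reach it through the modeling API.

Passing tests on this generator demonstrate recovery of planted structure
under the stated noise model; they do not establish performance on real
descriptor tables, whose columns are heavy-tailed, heteroscedastic, and
collinear in ways the generator does not emulate.

## Problem sizes and numerical choices

When the acceptance script evaluates the tuned mixed-kernel pipeline on
replicate synthetic datasets, it reports the held-out R² both over all test
compounds and restricted to test compounds whose leverage is at most h*.
The local trigonometric component cannot extrapolate outside the training
descriptor domain, and on some replicates a single high-leverage test
compound (correctly flagged by the Williams analysis) dominates the raw SSE;
the in-domain statistic is the one the applicability-domain methodology says
to trust.

The test suite and the acceptance script run synthetic problems at
n = 40–200 compounds with ≤ 12 descriptors, swarm budgets of 80–1500
evaluations (600 with 12 particles and 3-fold CV for the tuned mixed-SVR
pipeline), 20-seed Monte-Carlo loops for recovery rates, and ≤ 8-point
problems for the dual-QP oracle comparison — sizes at which every check
completes in seconds to a few tens of seconds on one core while leaving the
verified properties intact. Solver tolerances: 1e−8 for the raw dual QP
interface (1e−10 in the oracle comparison), 1e−4 with a 200k iteration cap
inside cross-validation fitness evaluations (failures become +∞ fitness),
and a patient 3M-iteration budget for one-off final refits. Degenerate
inputs are handled explicitly: constant targets yield zero duals and a mean
bias; constant descriptor columns get unit scale in standardization;
single-particle swarms learn from themselves; k = n folds reduce to LOO.
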