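# Methods

## Model and likelihood

The package models a semicontinuous outcome with a Bernoulli-Normal
two-part (hurdle) distribution: a logistic regression for the probability
π_i that the outcome is nonzero, and a normal linear regression for the
nonzero values.  Writing y_i for the nonzero indicator,

    l(θ) = Σ_i [ y_i z_i'β₁ − ln(1 + e^{z_i'β₁}) ]
         + Σ_{i: y_i=1} [ −(x_i − z_i'β₂)²/(2σ²) − ln σ − ½ ln 2π ]
         = l₁(β₁) + l₂(β₂, σ).

The additive split means the two parts never interact: every estimator in
the package fits them independently, and perturbing (β₂, σ) cannot change
the contribution of zero rows (a tested invariant).  The model assumes
the nonzero values are (possibly after a one-time log transform, the
`log_positives` flag applied at data construction) conditionally normal,
and that π is strictly inside (0, 1) — datasets with a single outcome
class are rejected rather than silently fit.

Both design matrices carry an explicit leading intercept column; q₁/q₂
always count non-intercept covariates.  Intercepts and σ are never
penalized.

## Maximum likelihood

The binomial part uses Newton iteration with the standard logistic score
U(β₁) = Σ (y_i − π_i) z_i and observed information Σ π_i(1−π_i) z_i z_i'
(for the logistic link this equals the Fisher information).  A
step-halving safeguard (up to 20 halvings) keeps the log-likelihood
non-decreasing between accepted iterates; convergence is declared when
the max-norm of the accepted update falls below `tol` (default 1e-8,
`max_iter` 100).  Quasi-separation — fitted probabilities within 1e-8 of
0/1 with a large coefficient norm — produces a warning, not an error.

Maximizing l₂ is exactly least squares on the nonzero rows, so the
continuous part is computed in closed form (normal equations plus the ML
variance σ̂² = n₊⁻¹ Σ residual²) rather than iterated; the one-step
solution is recorded in the same trace structure the Newton fit uses.
Score and information for (β₂, σ) are provided for diagnostics and are
validated against numerical derivatives in the test suite.

Linear predictors are clamped at |η| = 30 before exponentiation; beyond
that point π differs from 0/1 by < 1e-13, so the clamp is numerically
inert but prevents overflow.

## Penalized estimation

The selection methods minimize, per part,

    normal part:    Σ_{y=1} (x_i − z_i'β₂)² + λ₂ Σ_s ω₂s |β₂s|
    binomial part:  −2·l₁(β₁) + λ₁ Σ_j ω₁j |β₁j|

with ω ≡ 1 for the Lasso and ω_j = 1/|β̂_j,ml| (γ = 1) for the adaptive
Lasso, capped at 1e6 when the ML coefficient is below 1e-6.  The deviance
(−2l₁) scale for the logistic part is deliberate: the IRLS quadratic in
work-response form, Σ w_i (γ_i − z_i'β₁)², is the second-order expansion
of −2·l₁, so the weighted penalized least-squares problem the coordinate
updates solve and the stated objective agree exactly, mirroring the
normal part whose sum-of-squares objective is its deviance up to
constants.  (With the penalty attached to −l₁ instead, the same algorithm
corresponds to λ/2; since λ is tuned by cross-validation the two
conventions select identical models.)

The normal part is solved by cyclic coordinate descent: coordinate k is
updated to S(2 Σ z_ik r_ik^{partial}, λ₂ω₂k) / (2 Σ z_ik²) with
S(a,b) = sign(a)·max(|a|−b, 0), the intercept with a zero threshold.
The logistic part nests this inside an IRLS loop: the outer iteration
re-expands the quadratic at the current β₁ (weights floored at 1e-5 for
conditioning), the inner loop runs weighted coordinate descent with
coordinate curvature 2 Σ w_i z_ik² — the true second derivative of the
weighted quadratic.  A bisection safeguard toward the expansion point
keeps the penalized deviance non-increasing across outer iterations.
Excluded coefficients are exact (bitwise) zeros, and the solutions
satisfy the subgradient optimality conditions to tolerance; both solvers
are verified against a generic convex-programming solution
(positive/negative-part splitting + L-BFGS-B) to 1e-5 in objective value.

Convergence controls: inner sweeps stop when the largest coordinate
change is below 1e-7 (max 10 000 sweeps); the outer IRLS loop stops at a
max change of 1e-6 (max 50 iterations).  Hot loops are JIT-compiled.

### Regularization path and tuning

λ_max per part is the smallest penalty that zeroes every penalized
coefficient — max_j |2 Σ z_ij (x_i − x̄₊)| / ω_j on the nonzero rows for
the normal part, and max_j |2 Σ z_ij (y_i − ȳ)| / ω_j (the intercept-only
IRLS expansion, where the weights are constant and cancel) for the
logistic part.  The default grid is 100 log-spaced values descending from
λ_max to 10⁻³·λ_max, fit with warm starts; warm- and cold-started
solutions agree to tolerance (tested).

λ₁ and λ₂ are tuned separately by K-fold cross-validation (default
K = 10, random near-equal folds, fold seed independent of the data
generator).  Because the likelihood and the penalized problems separate,
each part gets its own held-out loss: mean binomial deviance on the
indicator for λ₁, mean squared error on the held-out nonzero outcomes for
λ₂.  The grid minimizer is selected, ties broken toward the larger
penalty; a 1-SE rule is available.  A joint alternative scoring the
combined prediction (x_i − π̂_i μ̂_i)² on the full 2-D grid is provided
(`cv_joint=True`); since the parts are fit independently the surface
factors into one path per part per fold, so it costs no extra fitting.
In the simulation designs below the separate and joint rules select
similar models; separate tuning is the default because each part's loss
is then a proper score for that part.

Adaptive-Lasso weights are computed once from the full-data MLE and held
fixed while λ is cross-validated: the weights are treated as part of the
penalty definition (a function of the dataset), not as a quantity
re-estimated inside each training fold.

## Prediction

The two-part expected outcome is x̂_i = π̂_i · μ̂_i.  The model itself
only defines E[X | X ≠ 0] = μ; the unconditional product form is the
standard two-part predictor and is used for cross-validated prediction
error and for the out-of-sample MPSE in the simulation harness.

## Synthetic data and the evaluation harness

The generator draws covariates from N_q(0, Σ) with Σ_ij = ρ^|i−j|
(exact AR Cholesky factor) and outcomes x_i = B_i · N(μ_i, 1) with
B_i ~ Bernoulli(π_i), logit π_i = z_i'β₁, μ_i = z_i'β₂, σ = 1, and the
same covariates in both parts.  Three preset designs are shipped:

* q = 10: β₁ = (0.2, 0.30, 1, 0.8, 0.4, −0.2, 0, …)', β₂ = (0.1, 1.10,
  1, −0.36, 0.6, 0, …)'
* q = 15: the same with an extra 0.6 (β₁) / 0.8 (β₂) signal at position 8
* q = 25: the q = 15 vectors extended with signals 1.1, −0.2, 0.6 (β₁)
  and 0.9, 0.7, 1.2 (β₂)

at n ∈ {150, 300} and ρ ∈ {0, 0.6}.  Because the normal factor is
unbounded, a "nonzero" draw can be negative; the nonzero indicator is
taken from the Bernoulli draw (equivalently y = (x ≠ 0)), which is what
the likelihood conditions on — real non-negative data are unaffected.
Note what this generator does *not* emulate about real semicontinuous
data: skewed or heteroscedastic nonzero values, covariate measurement
error, dependence between the two parts beyond shared covariates, and
missingness.  Passing tests therefore certify the estimation and
selection machinery under the stated model, not robustness to its
violations.

Each replicate draws an independent training and test set of the same n
from a stream derived only from (seed, replicate), fits every requested
method on identical data with identical folds (so method comparisons are
matched), and reports:

* MPSE on the test set — all-rows two-part error mean (x − π̂μ̂)²,
  nonzero-rows conditional error mean (x − μ̂)², and their sum
  (the part-wise attribution of prediction error is a convention of this
  package; only the additive combination is canonical);
* coefficient MSE per part, (q+1)⁻¹ Σ_{j=0..q} (β_j − β̂_j)², intercept
  included;
* selection Sensitivity (true signals kept), Specificity (true zeros
  dropped) and Accuracy ((kept + dropped correctly)/q) over the q
  non-intercept coefficients, with combined two-part versions pooling the
  numerators and denominators of both parts.

Replicates whose data degenerate (single outcome class, too few nonzero
rows, a single-class training fold) are redrawn from a shifted stream and
counted.  Default replication is 500; the shipped acceptance script uses
100 replicates per design, which puts the Monte-Carlo standard error of
the reported proportions near 0.01–0.02 while keeping a full run around a
minute on one CPU.

## Model comparison reporting

For a selected model the report gives, per part and summed, −2·LogLik,
AIC = −2l + 2k and BIC = −2l + k·ln(n_eff), where k counts the nonzero
coefficients of the selected model (intercept included, +1 for σ in the
continuous part) and n_eff is n for the binomial part and the number of
nonzero rows for the continuous part — a stated convention, since k and
n_eff admit alternatives post-selection.  ME is the K-fold
cross-validated prediction error of the selected model refit at its fixed
penalties.  A Shapiro-Wilk test on the (optionally log-transformed)
nonzero outcomes is offered as an advisory pre-check of the normal
continuous part; it never blocks fitting.

## Known limitations

* The continuous part is normal only; gamma or skew-normal alternatives
  and zero-part/positive-part dependence are out of scope.
* Designed for q ≪ n; nothing prevents q > n in the penalized path, but
  the MLE-based adaptive weights then do not exist.
* Adaptive-Lasso sensitivity for weak signals is limited by the sampling
  noise of the ML weights: a true coefficient whose ML estimate is
  unluckily small receives a large penalty weight and can be dropped.
  This is a property of the method, visible in the simulation results at
  small |β|·√n, not an implementation artifact.
* No standard errors or tests for the selected coefficients
  (post-selection inference is out of scope).
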