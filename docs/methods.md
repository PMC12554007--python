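# Methods

## Model

`methvc` maps regional methylation QTLs from bisulfite-sequencing counts.
For sample *i* at CpG position *t_ij*, the methylated read count
*Y_ij* out of *X_ij* total reads is modeled as

    Y_ij ~ Binomial(X_ij, pi_ij),
    logit pi_ij = beta_0(t_ij) + sum_{p=1..P} beta_p(t_ij) Z_ip,

where *Z_ip* in [0, 2] is the dosage of SNP *p* and every coefficient is a
smooth function of genomic position — a varying-coefficient model.  Each
function is expanded in a natural cubic spline basis of dimension *K*,
`beta_p(t) = theta_p' B(t)`, over positions affinely rescaled to [0, 1].

Only a few of the hundreds of candidate SNPs near a region are expected
to influence it, so the fit minimizes the twice-negative binomial
log-likelihood plus a composite group penalty

    lambda * sum_{p>=1} sqrt((1 - alpha) J1(beta_p) + alpha J2(beta_p)),

with `J1 = int beta_p^2 dt` (function size) and
`J2 = M^2 int (beta_p'')^2 dt` (curvature energy; `M` = total record
count, whose square puts the two terms on a comparable scale).  The square
root over the convex combination makes the penalty a generalized group
LASSO: whole coefficient functions are driven exactly to zero, while
`alpha` trades sparsity pressure against smoothness pressure.  `alpha = 1`
is rejected — a pure-curvature penalty ignores constant and linear
components and the problem can become unbounded.  The intercept curve
`beta_0` is never penalized.

In basis coordinates the penalty is `lambda * sum_p sqrt(theta_p' H theta_p)`
with `H = (1 - alpha) Omega1 + alpha Omega2`, where `Omega1` and `Omega2`
are the Gram matrices of the basis functions and of their second
derivatives.  Two special cases are exposed throughout: **SSP0**
(`alpha = 0`, metric `Omega1`) and **group LASSO** (`H = I`, penalizing raw
basis coefficients).

## Basis and penalty matrices

The basis is the *cardinal* natural cubic interpolation basis: `b_k` is
the natural spline that is 1 at knot *k* and 0 at the others.  Knots sit
at equally spaced quantiles of the distinct observed positions (robust to
irregular CpG spacing); boundary knots at the region ends.  Any natural
cubic basis spanning the same space yields identical fitted functions, so
all tests compare functions, never raw coefficients.

`Omega1` and `Omega2` are computed by per-interval Gauss–Legendre
quadrature: the integrands are piecewise polynomials of degree 6 and 2,
so 4 and 2 nodes per inter-knot interval are already exact; the test
suite verifies both against dense 20 001-point trapezoid oracles and the
node-count invariance.  `Omega1` is positive definite; `Omega2` is
positive semidefinite with a rank-2 null space (the linear functions).
`H` is factored as `H = L'L` (upper-triangular Cholesky, positive
diagonal); a jitter of `1e-10 * trace(H)/K` is added only if
factorization fails (possible as `alpha -> 1`).

Rescaling positions to [0, 1] before building the basis keeps `J1`/`J2`
magnitudes and the `alpha` grid comparable across regions of different
widths, complementing the `M^2` scaling.

## Optimization

With `eta_p = L theta_p` and transformed design blocks
`X~_p = X_p L^{-1}` (entries of `X_p` are `b_k(t_ij) Z_ip`), the problem
becomes smooth loss + plain Euclidean group norm, solved by proximal
gradient descent: `eta <- prox_t[eta - t grad l(eta)]`, where the proximal
map is group soft-thresholding `(1 - t*lambda/||u_p||)_+ u_p` (intercept
untouched).  The step size is found each iteration by backtracking on the
generalized gradient `G_t = (eta - prox_t(eta - t grad l))/t`, accepting
the first `t = t_init * shrink^m` with

    l(eta - t G_t) <= l(eta) - t grad l' G_t + (t/2) ||G_t||^2.

Numerical choices:

- **Initial step.** By default each line search starts at `1/L_hat`,
  where `L_hat = 0.5 * sigma_max(X~' diag(X) X~)` bounds the Lipschitz
  constant of the gradient (binomial variance is at most `X/4`),
  estimated by power iteration.  The first candidate step is then
  provably acceptable, so the search costs one objective evaluation in
  the common case.  A fixed `t_init` (e.g. 1) may be supplied; descent is
  guaranteed either way.
- **Ever-active-set screening.** Along a path most groups are zero.  The
  iterations run on the groups that are nonzero in the warm start; at
  convergence a full KKT sweep checks every zero group
  (`||grad_p l|| <= lambda`) and re-solves with any violators added.  The
  returned solution satisfies the same optimality conditions as a full
  solve — the tests verify KKT residuals directly — at a fraction of the
  cost.
- **Convergence** when the relative change of the penalized objective
  falls below `tol` (default 1e-8, `max_iter` 5000).  Objective-based
  tests are invariant to basis conditioning.
- **lambda = 0** is the unpenalized MLE and is solved by IRLS with
  step-halving rather than proximal iterations (plain gradient descent is
  needlessly slow on an ill-conditioned design; the optimum is identical
  and is checked against an independent GLM fit).
- Probabilities are clipped to `[1e-10, 1 - 1e-10]` before logs so line
  searches never see infinite objectives.
- Monomorphic SNPs (all-zero design block) are pinned at zero to avoid
  0/0 in the proximal map.

**lambda_max.** The smallest penalty at which every SNP group is zero
follows from the KKT conditions at the intercept-only fit:
`lambda_max = max_p sqrt(b_p' H^{-1} b_p)` with
`b_p = 2 X_p'(Y - diag(X) pi_0)`.  Paths use `L` log-spaced values from
`lambda_max` down to `tau * lambda_max` (defaults `L = 100`;
`tau = 0.01` when `M < (P+1)K`, else `0.001`), warm-starting each fit at
the previous solution; the intercept-only fit itself comes from IRLS with
step-halving.

## Tuning

(lambda, alpha) are chosen by K-fold cross-validation (default 5 folds,
12-point alpha grid `0, 0.1, ..., 0.9, 0.95, 0.99`) on the mean held-out
deviance `(1/M_o) sum -2[Y log pihat + (X - Y) log(1 - pihat)]`.  Folds
split **individuals**, not records — records within a sample share its
genotype, so record-level splits would leak.  The SE of the CV error is
the across-fold standard deviation of per-fold means divided by
`sqrt(n_folds)`.  Besides the global minimizer, the **1-SE rule** picks,
at the minimizing alpha, the largest lambda whose mean error is within
one SE of the minimum.  The lambda path is derived once from the full
data and reused across folds so fold errors are comparable point by
point.

**Adaptive variant.**  From an initial ordinary fit, per-covariate
weights `w1p = 1/sqrt(J1(betahat_p))`, `w2p = 1/sqrt(J2(betahat_p))`
re-scale the penalty metric per group,
`H_p = w1p (1-alpha) Omega1 + w2p alpha Omega2` (a direct consequence of
the weighted penalty's form; `lambda_max` then uses each group's own
`H_p`).  Covariates with a zero initial estimate are excluded outright.
A near-linear initial estimate has `J2 ~ 0`; its `w2` is capped at
`1/sqrt(1e-8 * J1)` so the metric stays positive definite without
excluding genuinely linear effects.  The recommended mapping mode is
adaptive SSP tuned under the 1-SE rule.

For real regions the SNP-effect basis dimension follows
`min(10, n_CpGs/10)` (clamped below at 4, the natural-cubic minimum),
with the intercept dimension fixed at 10.  The fitting pipeline uses one
shared dimension for all coefficient functions (the coefficient container
is a `(P+1) x K` matrix); `basis_dimension_rule` reports both numbers and
the shared-`K` default applies the SNP rule.

## Synthetic data

`methvc.simulate` emulates a targeted bisulfite-sequencing region under
exactly the assumed model: 123 irregularly spaced CpG sites across ~3 kb
(the per-scenario seed fixes the layout); genotypes from
thresholded-Gaussian haplotype pairs with block-diagonal LD (blocks of
20 SNPs, within-block exchangeable correlation `rho`, allele carried when
the latent Gaussian exceeds the `1 - maf` quantile; default
`maf = 0.3`); read depths Poisson with mean 30, truncated at 1; and
binomial methylated counts.  Of the P effect curves only `n_causal`
(default 5) are nonzero, cycling through closed-form shapes — constant,
linear, centered parabola, two-bump Gaussian mixture — plus a
piecewise-constant "sharp" shape that deliberately violates the
smoothness assumption; under `rho > 0` the causal SNPs are co-located in
one LD block.  The baseline curve is a smooth cosine with mean slightly
below 0.5 methylation.  Effect amplitude defaults to 1.0 on the logit
scale.

What the generator does **not** emulate: realistic LD from reference
panels, overdispersed (beta-binomial) counts, missing-at-random coverage
patterns, or bisulfite-conversion error.  Passing tests therefore show
correctness of the estimator under its own model assumptions, not
robustness to those artifacts.

## Evaluation measures

Estimation accuracy over R simulation runs on the CpG grid: integrated
squared bias, variance and MSE (`IMSE = IBIAS^2 + IVAR` identically;
sums over grid points).  Prediction on held-out records: deviance error
(mean excess of -2 log-likelihood of predictions over the truth — the
omitted binomial coefficient cancels), RMSE on the arcsine scale
`h(pi) = arcsin(2 pi - 1)`, and Pearson correlations of predicted versus
observed proportions on both scales (undefined correlations are returned
as missing).  Selection: TP/FP counts against the causal set.

## Replication study sizes

`methvc.study` re-runs the comparison of SSP vs SSP0 vs group LASSO (and
the 1-SE/adaptive variants) at desk scale: 4 runs of N = 50 samples,
123 CpGs, P = 100 SNPs (5 causal, smooth shapes, `rho = 0`), alpha grid
{0, 0.5, 0.99}, 15-value lambda path to `tau = 0.02`, 3-fold CV, solver
tolerance 1e-5; the basis-dimension companion uses 2 runs at K = 10
versus K = 30.  These sizes keep the full study in the minutes range on
one CPU.  With few runs the Monte-Carlo aggregates carry visible noise;
the study is used for ordering and ratio conclusions, not for the exact
magnitudes a full-size replication would give.

## Known limitations

- Plain (non-accelerated) proximal gradient descent: convergence is
  linear with a condition-number-dependent rate; FISTA-style momentum,
  coordinate descent and second-order solvers are out of scope.
- Binomial likelihood only — no beta-binomial overdispersion,
  measurement-error layer, or random effects.
- B-spline/wavelet bases and shape constraints are not provided; sharp,
  spiky effect patterns are fitted with visible bias (by design of the
  spline model), though selection remains mostly unaffected.
- The basis is built from the union of observed positions across samples;
  sample-specific CpG sets are supported at the record level.
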