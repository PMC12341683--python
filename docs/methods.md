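# Methods

## Model

`kansurv` estimates the log-partial hazard of a proportional-hazards model,

    h(t, x) = h0(t) * exp(theta(x)),

with a Kolmogorov-Arnold network (KAN): a composition of layers in which
every edge carries its own learnable univariate activation and every node
sums its incoming edges,

    x_{l+1,j} = sum_i phi_{l,j,i}(x_{l,i}),        theta(x) = KAN(x),

with a single scalar output node.  Each activation is

    phi(x) = w_b * b(x) + w_s * spline(x),

where `b` is a fixed basis function (SiLU by default, identity optionally)
acting as a residual path and `spline(x) = sum_i c_i B_{i,k}(x)` is a
degree-`k` B-spline on `G` uniform grid intervals with trainable
coefficients.  Defaults are `k = 3`, `G = 5` (3-5 supported in the search
space).  Because each edge is univariate, a trained network can be read
edge-by-edge, and each edge can be replaced by a closed-form expression —
that is the entire point of the architecture.

Assumptions inherited from the proportional-hazards frame: covariates act
multiplicatively on a shared baseline hazard, their effect is constant in
time, and censoring is non-informative.

### Grid domain and normalization

Input-layer splines live on [-1, 1]; inputs are mapped there by a
per-feature affine transform fitted on the training split only and stored
in the model, so the identical transform applies at test time (leakage
guard).  Hidden-layer splines use a wider fixed grid ([-3, 3] by default)
because node sums are not re-normalized during training; grid refinement
from data, as in the original KAN formulation, is deliberately not
implemented — `G` is fixed per run.  At inference, inputs outside the grid
are clamped to the grid boundary *for the spline term only*; the basis term
`w_b b(x)` is evaluated on the raw input so gradients keep flowing in the
tails.

Parameters initialize to `w_b = w_s = 1` with spline coefficients i.i.d.
N(0, 0.1^2) under a seeded generator; every stochastic choice in a run
(initialization, splits, search sampling) derives from one seed.

## Objective

Training minimizes the fast Cox loss plus a sparsity regularizer:

    l_total = l_cox + lambda * R
    R = sum_l |Phi_l|_1 + lambda_ent * sum_l S(Phi_l)
        + lambda_coef * sum_l |C_l|_1

* `|phi|_1` is the batch-mean absolute post-activation of an edge;
  `|Phi_l|_1` sums a layer's edges.
* `S(Phi_l)` is the Shannon entropy of the normalized edge-L1 distribution;
  penalizing it concentrates activity on few edges.
* `|c|_1` is the mean absolute spline coefficient per edge; penalizing it
  favors smoother activations.

The exposed `total_loss` uses the summed Cox loss exactly as written above.
Inside the training loop the Cox term is divided by the number of events so
that `lambda` has the same meaning at n = 500 and n = 10 000; this changes
only the scale of the objective, not its minimizer at fixed `lambda`, and
keeps the search range `lambda in [1e-5, 1e-1]` size-independent.

### Fast Cox loss

The exact negative log partial likelihood needs the risk set
`R(t_i) = {j : t_j >= t_i}` per event.  The fast variant sorts subjects
once by descending duration (stable, events before censored subjects at
equal times) and obtains every event's denominator from a running
log-cumulative-sum-exp in O(n log n).  With distinct durations it is
exactly the Breslow partial likelihood (tested to 1e-10); with ties the
prefix under the sorted order stands in for the risk set — a documented
approximation whose tie convention is fixed by the sort rule above.  Both
losses and their analytic score gradients use log-sum-exp arithmetic
throughout; the gradients are verified against finite differences in the
test suite.

## Training

Full-batch Adam (the target datasets are small; full batches also make the
within-split risk sets exact), one step per epoch, with early stopping on
the validation C-index and the best-validation checkpoint returned.
Defaults: learning rate 0.02, patience 30 epochs, validation fraction 0.2
(split stratified on event indicator x duration quartile), `lambda_ent = 2`,
`lambda_coef = 0.5`.

One refinement matters in practice: the validation C-index plateaus within
a few dozen epochs, while the regularizer needs several hundred more to
shrink irrelevant activations, and on the plateau the C-index fluctuates by
a few thousandths from epoch to epoch.  Selecting the literal argmax
therefore freezes an arbitrary, barely-regularized early checkpoint.  With
`checkpoint_tol > 0`, any later epoch whose validation C is within the
tolerance of the running best refreshes the checkpoint — among
statistically indistinguishable checkpoints the most-trained one wins.  The
default is 0 (exact argmax); the synthetic benchmark uses 0.005, about the
Monte-Carlo noise of a C-index on its validation sizes.

Hyperparameter search is seeded random search scored by k-fold
cross-validated mean C-index (the held-out fold doubles as the
early-stopping set); shapes {[p,1], [p,1,1], [p,2,1]}, `G in {3,4,5}`, and
log-uniform `lambda` and learning rate by default.  A Tree-structured
Parzen Estimator could sit behind the same interface; random search is the
reference implementation.

## Pruning

Edge L1 norms are computed on the full training set (deterministic
decisions, not batch noise).  Edges below the threshold are switched to a
pruned state (exactly zero); a hidden node whose incoming *or* outgoing
edges are all pruned is removed structurally, cascading.  Because removing
an edge shifts every downstream edge's activation distribution, the
mark-and-cascade pass repeats with freshly computed norms until stable —
this is what makes pruning idempotent.  Input features with no surviving
outgoing edge are reported as deselected: automatic feature selection.

The automatic threshold scans 20 log-spaced candidates between the smallest
and largest observed positive edge norm and keeps the best validation
C-index.  Differences below `tie_tol` count as ties, broken toward the
larger threshold (the sparser network): a sub-resolution gain in C never
justifies extra edges.  Exact ties essentially never occur on a continuous
C-index, so a literal tie-break rule would be vacuous without the
tolerance.

## Symbolic distillation

Each retained edge is fitted against its own pre/post-activation pairs
(up to 512 points, quantile-spaced), progressively:

1. **Linear**: least-squares line, accepted if R^2 > 0.99.
2. **Operator library**: `phi(x) ~= c f(ax + b) + d` for each of 22
   univariate operators (powers, reciprocals, sqrt/log/exp, trig and
   inverse trig, tanh/sigmoid/sign/step, a Gaussian bump, a constant); (a, b)
   from a 42 x 21 log/linear grid with (c, d) solved by linear regression,
   grid points violating an operator's domain excluded for that operator.
   The top three grid candidates are polished by Nelder-Mead on all four
   parameters and the best refined fit wins — the coarse grid can rank a
   flexible operator (e.g. sin) above the true one before refinement.
   Accepted if R^2 > 0.95.  Note that (a, b, c, d) carries gauge freedom
   for several operators (for exp, only `a` and `c e^b` are identifiable),
   so fits should be compared functionally, not parameter-wise.
3. **Genetic fallback**: in-process genetic programming over expression
   trees with {+, -, *, /, sin, cos, exp, log, abs, square, sqrt}, protected
   numeric semantics, tournament selection, subtree crossover/mutation and
   a complexity penalty.  The initial population is seeded with
   `u(c x)` / `x u(c x)` templates for every unary operator, and the best
   structurally distinct finalists get a Nelder-Mead polish of their
   constants — structure discovery is the hard part; constant tuning is
   cheap.  Deterministic under its seed; if the budget ends below the
   target R^2 the best expression is returned with a warning flag.

Categorical features bypass all three stages: a label-encoded feature only
ever presents its level codes to the edge, so the exact symbolic form is
the finite code-to-value map obtained by evaluating the trained edge at the
encoded positions.

`extract_formula` composes the per-edge expressions through the layer
structure into one sympy expression for theta(x), expands it, and ranks
top-level terms by their standard deviation sigma over a reference dataset
(the partial likelihood ignores constants, so a term's variation — not its
level — measures its influence; constant terms report sigma = 0 and are
dropped from the ranking).

## Linear CoxPH baseline

`fit_coxph` maximizes the Breslow partial likelihood, optionally with a
Lasso penalty, by FISTA: accelerated proximal gradient with backtracking
line search and adaptive restarts.  The proximal step gives exact zeros
under L1 (soft thresholding); with no penalty the method reduces to
accelerated gradient descent with line search.  Convergence is declared at
a 1e-7 max-norm proximal residual on the event-averaged objective;
non-convergence raises an error carrying the final residual, and coefficient
norms beyond 100 trigger a perfect-separation warning.  Wald standard
errors come from the observed information at the optimum; they drive the
univariate screening p-values.

## Synthetic data generator

The simulator draws covariates uniformly on [-1, 1], evaluates a symbolic
log-partial hazard theta(x), and samples event times exactly by inverse
transform: with constant baseline hazard h0 (default 0.01),
S(t|x) = exp(-h0 e^theta t), so `T = -ln(U) / (h0 exp(theta))`.  Censoring
is uniform on [0, c_max]; the observed duration is min(T, C) with event
indicator 1[T <= C].  Two irrelevant noise covariates are appended from
the same sampler but never enter theta.  The default c_max solves for 30%
censoring under theta = 0 (c_max ~= 320 at h0 = 0.01); under a non-null
theta the realized censoring fraction is lower because events arrive
earlier.

Four benchmark families are built in: a radially symmetric Gaussian bump
(no linear signal — the CoxPH baseline is blind to it), an additively
separable "mixed" family (trigonometric + polynomial + linear), a Euclidean
distance from the origin, and a "complex" family with logarithms, absolute
values and cross-term interactions.  Their exact published definitions live
in external supplementary material; the formulas here are documented
stand-ins matching the stated family descriptions and are flagged
`standin: true` in the metadata:

    gaussian   theta = 2 exp(-(x1^2 + x2^2))
    mixed      theta = sin(pi x1) + x2^2 + x3
    euclidean  theta = 2 sqrt(x1^2 + x2^2 + x3^2)
    complex    theta = log(1 + |x1 x2|) + |x3| x4^2

What the generator emulates: proportional hazards with a known ground
truth, realistic censoring, and irrelevant covariates for the feature
selector to find.  What it does not emulate: tied event times (durations
are continuous, so the fast-loss tie approximation is never stressed by it),
time-varying effects, informative censoring, correlated or heavy-tailed
covariates, and missingness.  Passing the synthetic benchmark therefore
demonstrates recovery of the generating mechanism under the model's own
assumptions, not robustness to their violation.

## Benchmark conditions

The benchmark runs each family at n = 10 000 train / 10 000 test (the
test suite scales down to 3 000, except 6 000 for the weak-signal complex
family, which needs the larger sample before the regularizer separates
noise from its faint interactions).  Shapes follow each family's structure:
[p,1] for the separable mixed family, [p,1,1] for the two radial families,
[p,2,1] for complex.  Training uses lambda = 0.01 with learning rate 0.05
(complex: 0.03), 800 steps with patience 100 (complex: 500 steps with
early stopping disabled — its validation C plateaus immediately while
regularization cleanup takes several times longer), checkpoint and pruning
tie tolerances of 0.005.  Under these conditions pruning removes both
noise covariates on every family across seeds, and the symbolized model's
test C-index tracks the true formula's within ~0.007.

The true-formula C-index is the ceiling statistic: survival time is a
random variable, so even the generating formula does not reach C = 1, and
no proportional-hazards ranker can beat it asymptotically.

## Numerical choices and edge cases

* Harrell's C counts a pair (i, j) when `t_i < t_j` and subject i had an
  event; score ties count 1/2; an all-tied score vector scores exactly 0.5.
  The pair counting is a compiled O(n^2) kernel (numba).
* Bootstrap confidence intervals are percentile 2.5/97.5 over subject
  resamples (1000 by default, seeded); degenerate resamples with no
  admissible pairs are skipped with a warning, and the interval is widened
  minimally when the percentile band would exclude the point estimate.
* Entropy uses the 0 log 0 = 0 convention and is defined as 0 for an
  all-zero layer.
* R^2 of a constant target is 1 for an exact fit, else 0.
* Division, log, sqrt and similar operators use protected or domain-clamped
  numerics at inference; fitting-time grids simply exclude out-of-domain
  candidates.
* Model checkpoints are JSON with shortest-repr floats, so serialization
  round-trips bit-exactly.

## Known limitations

* No grid refinement during training; strong out-of-range drift at hidden
  nodes is handled only by the clamp + residual-basis path.
* The tie approximation of the fast loss is a different estimand than
  Efron or exact Breslow when heavy ties exist; use `cox_loss_exact` for
  heavily discretized durations.
* Pruning thresholds selected on a validation set reuse the same split as
  early stopping; the tie tolerances absorb most of the resulting
  optimism, but an untouched test set remains the only honest scoreboard.
* Gradient training through symbolized or categorical-mapped edges is not
  supported; symbolize last.
* Genetic search explores univariate expressions per edge only; it cannot
  repair an interaction the network structure failed to separate.
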