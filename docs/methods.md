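# Methods

This note documents the models implemented in `iaoadbn`, the choices made
where the underlying method descriptions were ambiguous, and what the
synthetic data can and cannot show.

## Archimedes optimization algorithm

Each of `n` materials carries a position `x_i` in the box bounds, a scalar
density `den_i` and volume `vol_i` (uniform in (0,1) at start), and a
per-dimension acceleration `acc_i` (uniform on the bound scale at start).
Per iteration `t` of `t_max`:

* transfer factor `TF = exp((t − t_max)/t_max)` (rises to 1) and density
  factor `d = exp((t_max − t)/t_max) − t/t_max` (falls to 0);
* densities and volumes relax toward the incumbent's:
  `den_i ← den_i + r(den_best − den_i)`, same for volume, fresh uniform
  draws per material and quantity;
* acceleration: for `TF ≤ 0.5` (exploration)
  `acc_i ← (den_mr + vol_mr·acc_mr)/(den_i·vol_i)` with `mr` a uniformly
  random material; otherwise the incumbent's quantities replace `mr`'s.
  The product `den_i·vol_i` is floored at 1e-12 and the result clipped to
  ±1e100 (repeated division by small products otherwise overflows; the
  subsequent normalization is scale-free, so the cap is inert in normal
  operation);
* accelerations are min-max normalized over the whole population into
  `[l, u+l] = [0.1, 1.0]`. A numerically degenerate range (spread below
  1e-9 relative) collapses to `l` rather than amplifying 1-ulp noise;
* positions: exploration steps toward a random material,
  `x_i ← x_i + C1·r·acc_norm_i·d·(x_rand − x_i)`; exploitation anchors at
  the incumbent, `x_i ← x_best + F·C2·r·acc_norm_i·d·(T·x_best − x_i)` with
  `T = C3·TF` and direction flag `F = +1` iff `2r − C4 ≤ 0.5`. Positions
  are clipped to the bounds component-wise and the incumbent updated after
  re-evaluation.

Defaults `C1 = 2, C2 = 6, C3 = 1, C4 = 2`, `u = 0.9, l = 0.1`, population
30, 500 iterations. Note that with `C4 = 2` the direction flag is
constantly +1; the flag is kept as specified, and the consequence (the late
exploitation phase can only contract the incumbent along the ray toward the
origin) is discussed under *Known limitations*.

Three details are deliberate implementation decisions where the method
description is silent, each selected by benchmarking all alternatives:

1. **The incumbent stores its normalized acceleration.** Storing the raw
   value feeds back through the division by `den·vol < 1` at every
   incumbent change and diverges within a few hundred iterations.
2. **One scalar uniform draw per material in the position updates.** The
   scalar draw makes exploitation steps whole-vector contractions anchored
   at the incumbent: when the population has collapsed onto `x_best`, every
   sample is a pure scaling `x_best(1 − c(1−T))`, which is monotonically
   improving for origin-centred objectives and produces the deep geometric
   convergence the algorithm is known for (sphere reaches ~1e-16; per-
   dimension draws stall nine orders of magnitude earlier and never reach
   Griewank's exact-zero basin).
3. **The canonical exploitation displacement `T·x_best − x_i`.** The
   alternative reading `T·(x_best − x_i)` is a pure contraction around the
   incumbent; measured head-to-head it collapses the population before the
   incumbent is good (sphere stalls at 1e-2, Griewank never reaches zero).
   A config switch `exploit_form="as_printed"` retains the alternative.

## Improved variant (IAOA)

Initialization: one sine-chaos stream `x_{t+1} = sin(2/x_t)` per dimension
(seed value uniform in [−1,1]\{0}, 100 burn-in iterates, exact zeros
reseeded), mapped affinely onto the bounds; the population is mirrored
through its own per-dimension min/max (opposition with a dynamic boundary,
not the static bounds) and the fitter half of the union seeds the run.

Per iteration, after the AOA update, the incumbent is perturbed
multiplicatively, `candidate = x_best ⊙ (1 + g)` with one independent
`N(0, σ)` draw per dimension, and replaces the incumbent only when a
uniform draw falls below `p` *and* the candidate is strictly better.
`p = 0.5` and `σ = 1` by default (neither value is prescribed anywhere;
both are configurable). The multiplicative form cannot move a coordinate
that is exactly 0 — a documented pathology covered by a test.

On 30-D Griewank the combination reaches an exact `0.0` in IEEE doubles:
once every coordinate falls below ~1.5e-8 the cosine product rounds to 1.0
and `s − p + 1` cancels exactly; the elite mutation's accepted shrinkages
compound geometrically once the incumbent is in the origin basin.

## MRMR feature ranking

Mutual information is the plug-in estimate (base 2) from the contingency
table of discretized columns; continuous columns use equal-frequency
binning with 10 bins by default (configurable — the right bin count for
clinical blood indicators is not derivable from first principles).
Relevance of a set is the mean feature–label MI; redundancy is
`(1/|S|²) Σ_{i,j}` over *ordered pairs including the diagonal*, as the
double sum is conventionally written. The diagonal terms make a feature's
own entropy part of its redundancy, which systematically favors
low-entropy (discrete) features; `include_self=False` switches to the
diagonal-free convention.

Greedy selection: step 1 maximizes `I(x; C)`; step 2 minimizes the
redundancy of the selected pair (a pure minimum-redundancy step, per the
procedure this package follows; `step2="mid"` applies `Φ = D − R` from
step 2 onward instead); later steps maximize `Φ` of the augmented set.
All ties break toward the lower column index, making rankings
deterministic given the data.

The incremental-subset procedure scores each ranking prefix with a
single-hidden-layer feedforward classifier (16 units, scaled inputs,
L-BFGS, seeded) under stratified 10-fold CV and returns the smallest
prefix attaining the maximum of the curve.

## Deep belief network

Bernoulli RBMs with energy `E(v,h) = −v'Wh − a'v − b'h`; conditionals are
logistic sigmoids (the rising form `1/(1+e^{−x})`). CD-1: hidden
probabilities from the data, a Bernoulli sample drives one reconstruction,
and the update is the learning rate times the batch-mean difference of
`⟨v h⟩` statistics — probabilities are used in both correlation terms
(standard variance reduction; `sample_hidden=False` disables sampling
entirely, which is what the exact-enumeration tests exercise). Layers are
pretrained greedily on the previous layer's activation probabilities.

Supervised stage: a 2-unit softmax head on the top hidden layer,
cross-entropy backpropagated through every layer with minibatch SGD and
classical momentum 0.9 (the standard recipe for fine-tuning CD-pretrained
stacks; without it, small nets at desk-scale epoch budgets sit at the
symmetric all-0.5 saddle over much of the hyperparameter plane, which
would turn the tuning landscape into a plateau). Weights initialize as
`N(0, 0.01)` (variance 0.01, sd 0.1), biases at zero. Continuous inputs
are min–max scaled to [0,1] and treated as visible probabilities; no
Gaussian visible units.

Defaults: hidden stack (64, 32), learning rate 0.1, batch size 16, 50
pretraining and 100 fine-tuning epochs, CD-1. The depth, widths and epoch
counts are engineering choices (nothing in the method description fixes
them); they are all surfaced in `DbnConfig`.

## Hyperparameter search

The search space is the unit square: the first coordinate maps
log-uniformly onto the learning rate α ∈ [0.001, 0.5], the second linearly
onto the integer batch size β ∈ [4, 64] by nearest-integer rounding, with
clipping (ranges chosen to cover standard CD learning rates and feasible
batch sizes for ~270 training rows). Fitness of a candidate is its
validation accuracy: a DBN with the decoded (α, β) trains on the fold's
training part and is scored on a stratified 20% inner validation split;
the optimizer minimizes the error rate. Each outer fold of a stratified
10-fold protocol holds out its test part entirely — fitness never sees it —
and the winning (α, β) retrains on the whole remainder. Per-fold seeds
derive deterministically from the protocol seed; identical decoded
candidates are cached within a fold. Default search budget: population 20,
30 iterations (500 iterations is the figure used for the benchmark
functions; at 600+ network trainings per fold it is disproportionate for
this 2-D space, so 30 is the default and both values are configurable).

Desk-scale problem sizes used by the test suite: the tuned-vs-default
comparison runs the full default architecture with search budget
population 8 × 6 iterations; the paired-seed optimizer comparison and the
feature-subset comparison run a compact stack ((16, 8), 10 pretraining /
60 fine-tuning epochs) with 5 outer folds and population 5 × 4 iterations.

## Synthetic cohort generator

The flagship preset emulates a 298-patient ESCC cohort: 17 blood
indicators plus age as truncated normals, T/N/TNM staging as categorical
draws with the published category proportions, and a binary five-year
survival label. Choices worth spelling out:

* **Moment-matched truncation.** A truncated normal parameterized naively
  by the published mean/sd does not *have* that mean/sd once truncation is
  asymmetric (for a count piled at zero the realized mean shifts by half a
  standard deviation). Each indicator's (loc, scale) is therefore solved by
  analytic moment matching so the truncated distribution itself hits the
  published mean and sd. For two boundary-skewed counts (BASO, EO) the
  published sd exceeds what any truncated normal on that range admits at
  that mean; the closest achievable moments are used (deviations ≤ 0.07).
* **Stratified sampling.** Continuous columns are drawn by inverse-CDF over
  a Latin-hypercube stratification of [0,1], giving the same marginal law
  as iid draws but with empirical-moment error of order 1/n instead of
  1/√n. With an explicit correlation matrix the generator switches to a
  Gaussian copula with plain Monte Carlo draws.
* **Label planting.** The label is Bernoulli of a logistic score over 11
  designated signal indicators (z-scored, fixed coefficients whose signs
  follow clinical direction; magnitudes are engineering choices recorded in
  the preset YAML), rescaled so the cohort's Bayes accuracy is ≈ 0.90 —
  the operating regime of the classifiers under study. When an exact
  positive count is requested (147/298 in the preset) the fewest, least
  improbable label flips enforce it. Age splits ~64/36 at 61.5 years by
  construction (mean 57.5, sd 11 on [38, 82]).
* **Independence.** Indicators are independent by default: no covariance
  information is available for the real cohort, and inventing one would
  manufacture unfalsifiable structure. Consequences: feature–feature
  redundancy is low, so MRMR behaves more "optimistically" than on real
  blood panels, and feature selection cannot exploit correlated backups —
  dropping a weak signal feature always costs signal. Passing pipeline
  tests on this cohort demonstrate correctness of the machinery and the
  *ordering* of methods, not clinical performance.

## Known limitations

* With `C4 = 2` the exploitation direction flag never flips, so the late
  AOA phase refines only along the ray toward the origin; precision at
  *non-origin* optima (Kowalik, six-hump) comes from the elite mutation,
  whose fixed relative step size bounds the attainable excess over the
  optimum (Kowalik stalls ~1e-4 above it). Deep convergence at
  origin-centred optima is unaffected.
* The elite mutation cannot escape an exactly-zero coordinate
  (multiplicative form).
* The generator controls marginals and a linear-logistic signal only; no
  survival times, no missingness, no inter-indicator correlation unless
  supplied explicitly.
* MRMR at n ≈ 300 with 10-bin MI estimates has a detection floor around
  0.02 bits; indicators carrying less than ~8% of the signal variance can
  drop out of the top-k in favor of noise columns. This is a property of
  plug-in MI at small n, not of the greedy procedure (which matches
  exhaustive enumeration exactly in the oracle tests).
* Binary labels only; multi-class is config-gated but untested.
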