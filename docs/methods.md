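# Methods

`uqmd` quantifies two distinct sources of uncertainty in ensemble molecular
dynamics observables such as ligand–protein binding free energies:

- **parametric (epistemic) uncertainty**, induced by uncertain simulator
  inputs (thermostat temperature, barostat target, cutoffs, durations, …),
  modelled as independent uniform random variables; and
- **aleatoric uncertainty**, induced by the random seed that sets initial
  velocities: chaotic dynamics turn the seed into an irreducible noise
  source that must be quantified with replica ensembles.

The simulator is treated as a black box `(configuration, seed) → energy`.
The package propagates the input distributions through it with
dimension-adaptive stochastic collocation, decomposes the output variance
into Sobol indices, and characterizes the seed-driven spread with
probability boxes, shape statistics and coefficient-of-variation ratios.

## Stochastic collocation on sparse grids

All quadrature lives on the unit hypercube `[0,1]^d` under the uniform
probability measure; the affine map to each input's physical `[lo, hi]`
interval belongs to the input space. One-dimensional rules are nested
Clenshaw–Curtis rules with growth `m(0) = 1`, `m(l) = 2^l + 1`: the level-0
rule is the single midpoint, so an adaptive campaign starts from one
configuration at the center of the input box. Weights are normalized to sum
to one (quadrature with respect to a probability measure, not interval
length). An `m`-point rule integrates polynomials up to degree `m − 1`
exactly.

A sampling plan is a downward-closed set Λ of quadrature-order
multi-indices. The surrogate is the combination-technique interpolant

    I(x) = Σ_{l ∈ Λ} c_l I_l(x),    c_l = Σ_{z ∈ {0,1}^d, l+z ∈ Λ} (−1)^{|z|},

where `I_l` is the tensor-product Lagrange interpolant on the grid of index
`l`. The coefficients sum to one, so constants are reproduced exactly, and a
full box Λ telescopes to its corner tensor grid. Because the 1D rules are
nested, coincident points across member grids are bitwise identical and
deduplication uses exact coordinate equality — no tolerance is involved.

**Moments.** The surrogate mean is the sparse quadrature of the node
values. The variance is the sparse quadrature of the *squared* surrogate on
the same plan (which, by the interpolation property on the union grid,
is the quadrature of the squared node values) minus the squared mean,
clipped at zero. This choice is self-consistent with the interpolant and
testable against Monte Carlo; it is exact once the plan's rules cover twice
the surrogate's degree, and approximate otherwise.

## Dimension-adaptive refinement

Starting from Λ = {(0,…,0)}, the sampler alternates a *look-ahead step* —
evaluate the simulator ensemble at the new unique points of every
admissible forward neighbor of Λ — with acceptance of the candidate whose
error measure

    ε_l = | Var(Λ ∪ {l}) − Var(Λ) |

is largest, ties broken by the lexicographically smallest index. The
refined quantity of interest is the ensemble average of the energy over the
fixed seed list (a single-seed mode supports no-ensemble campaigns). All
`(configuration, seed)` evaluations are cached, so nesting never causes a
duplicate simulator call, and every evaluation — look-ahead included —
counts against the budget at the moment it is made. The loop stops when the
next look-ahead would exceed the budget, when no candidates remain, when an
optional absolute tolerance on `max ε` is reached, or when no candidate
changes the variance at all.

Numerical choices worth knowing:

- **Noise floor.** An ε below `1e−12 × (mean² + variance)` is treated as
  exactly zero. The combination terms of an inert dimension cancel
  mathematically but leave a summation residue of order machine-epsilon
  times the second moment; without the floor that residue could steer
  refinement into dimensions the output does not depend on.
- **Zero-gain candidates** stay in the candidate pool: later acceptances
  can change their error. They are, however, never accepted by the default
  greedy policy, which keeps refinement of additive low-effective-dimension
  models confined to their active inputs.
- **Exploration mode** (`explore=True`, off by default). The variance
  metric is blind to any direction in which the model coincides with the
  current surrogate on the candidate grid — notably models that vanish
  identically on the center hyperplane, as both classic benchmarks below
  do. In exploration mode, once `max ε` falls below `explore_rtol`
  (default 0.1) times the current variance, the sampler accepts the
  cheapest not-yet-accepted candidate instead, opening interaction
  directions at the cost of occasionally refining inert dimensions. The
  default threshold trades exploitation of a slowly-converging direction
  (e.g. a kinked response) against discovery of unseen ones; it was chosen
  so that both benchmark recoveries below succeed at desk-scale budgets
  and is insensitive to the budget over the ranges we tested.

## Sobol indices

The surrogate is re-expressed in the tensor-Legendre basis orthonormal
under the uniform measure. Each member interpolant is a polynomial of
per-dimension degree `m_i − 1`, so its projection onto the first `m_i`
orthonormal Legendre polynomials per dimension (computed with Gauss–
Legendre quadrature of sufficient order) is exact; the signed combination
coefficients assemble the global expansion, which therefore *equals* the
surrogate everywhere. Parseval's identity then gives the total variance `D`
as the sum of squared coefficients over nonzero degree tuples, the partial
variance `D_u` of an input subset `u` as the sum over tuples whose support
is exactly `u`, and Sobol indices `S_u = D_u / D`. Indices over the full
power set are aggregated up to `d = 6`; beyond that only subsets of order
≤ 2 are reported (the power set explodes, and first-order effects dominate
in the intended applications). A constant surrogate has `D = 0` and is
flagged undefined rather than propagating NaNs.

Validation anchors: the Sobol g-function (closed-form indices from
`D_i = (1/3)/(1+a_i)²`) and the Ishigami function (closed-form variance
decomposition, including the pure-interaction index of its third input).

## Aleatoric analysis of replica ensembles

For a complete campaign table — every configuration evaluated with the same
seed list — three views exist: the raw energies (`n_config × n_seed`), the
per-seed averages over configurations (aleatoric view), and the
per-configuration ensemble averages (epistemic view).

**Probability box.** Fixing a seed and sweeping configurations yields one
empirical cdf per seed; the p-box is the pointwise min/max envelope of the
family. Central intervals are read off the envelopes with the
left-continuous generalized inverse `F⁻(q) = min{x : F(x) ≥ q}` (computed
with a relative tolerance on the order-statistic index so that binary
levels such as 0.025 land on the intended sample). The envelope interval
contains the corresponding interval of every member cdf, hence is
conservative by construction; per-member intervals are also reported so the
spread among individual fixed-seed analyses is visible.

**Shape statistics.** Per-configuration skewness `m₃/m₂^{3/2}` and excess
kurtosis `m₄/m₂² − 3` use biased moment-based estimators by default (the
Gaussian references 0 and 3 hold for either variant at large n; the
bias-corrected variant is available via `bias=False`). Confidence intervals
are percentile-bootstrap over replicas within a configuration (default 2000
resamples, 90% level, explicit integer seed; each configuration derives its
own independent resampling stream). Ensembles are binned by |skewness|:
region A < 0.5 (approximately symmetric), B in [0.5, 1.0] (moderately
skewed), C > 1.0 (highly skewed). Zero-variance ensembles are flagged
undefined. Kernel density summaries (Gaussian kernel, Scott's bandwidth)
are provided for presentation only and feed no statistic.

**Coefficient-of-variation ratio (CVR).** Input CVs are analytic
(`(hi−lo)/√12` over the midpoint, absolute value); the mean input CV
averages over the `d` inputs, never the seed. The output CV is taken either
over per-configuration ensemble means (*ensemble* mode) or per seed over
configurations with the absolute values averaged (*per-seed* mode);
`CVR = CV_out / CV_in_mean`, with CVR > 1 flagging amplification. Sample
standard deviations use the `n − 1` denominator (configurable). Because
averaging over seeds removes aleatoric spread, the mean of the per-seed
standard deviations always dominates the standard deviation of the
ensemble mean; for the CVs themselves the division by per-seed means
weakens this domination by the factor `|mean_s μ_s| / max_s |μ_s|`, so the
per-seed CVR can undercut the ensemble CVR by a fraction of a percent in
small samples, and dominates it whenever the output mean dwarfs the
seed-to-seed mean differences — the regime binding energies live in. A `assume_pm15` flag treats every
input — including one with a specially restricted range — as ±15% about its
nominal (CV = 0.15/√3 ≈ 0.0866 each, mean rounding to 0.087), matching the
bookkeeping convention of the published summary table.

## The synthetic simulator

`synthetic.mock_esmacs` stands in for the MD engine so the pipeline can be
exercised end to end in milliseconds. Its default input space has 14
uniform parameters: 13 at ±15% about placeholder nominal values (explicitly
non-physical; they only define the affine map) and the thermostat
temperature on [280 K, 320 K] about a 300 K nominal. The energy model is

    e(ξ, η) = base + trend(ξ) + scale · z(η),

with `base = −34.5` kcal/mol, a linear/quadratic trend active in three
inputs (temperature dominant: coefficients 1.4, 0.5 and 0.25 kcal/mol per
unit-cube deviation, plus a 0.3 kcal/mol quadratic in temperature) and a
standardized skew-normal noise draw (shape α = 3, scale 1.5 kcal/mol)
indexed by the seed alone. The per-seed variate is the base-2 radical
inverse of `seed + 1` pushed through the skew-normal quantile function:
deterministic, free of global random state, and low-discrepancy, so that a
modest fixed seed list (default seeds 1–25, reused for every configuration)
carries spread and skewness representative of the noise family — emulating
an ensemble size chosen to give stable statistics.

With these defaults a 63-configuration × 25-seed campaign lands near the
intended study conditions: pooled mean within 0.5 kcal/mol of −34.5, pooled
spread of order 1–2 kcal/mol, mildly positive ensemble skewness, and a low
effective dimension led by temperature. Because the noise depends on the
seed only, per-seed cdfs are exact translates of one another (a maximally
coherent p-box) and ensemble averaging cannot reduce the per-seed spread;
two knobs plant configuration–seed interaction when the contrast between
per-seed and ensemble-averaged variability is the object of study:
`skew_mean_coupling` drifts the noise shape with the local trend, and
`noise_mixing ∈ [0,1]` blends in a variate hashed from the (configuration,
seed) pair — at 1 the noise is independent across configurations and
ensemble averaging shrinks the output CV by roughly the square root of the
ensemble size.

What the generator does *not* emulate: force-field physics, correlation
structure between inputs, configuration-dependent noise scale, and the
specific numerical values of any published MD campaign. Tests passing on
the mock therefore validate the statistical machinery and its contracts,
not the behavior of any particular MD code.

## Problem sizes

Default test and demonstration campaigns use desk-scale budgets — hundreds
of simulator calls, ensembles of 5–25 replicas, 63 configurations for the
fixed-plan bookkeeping — chosen so the full pipeline runs in seconds while
still exhibiting the phenomena of interest (anisotropic refinement,
envelope widening, CVR damping).

## Known limitations

- The variance quadrature is approximate for surrogates whose squared
  degree exceeds the plan's exactness; Parseval consistency between the
  expansion-based and quadrature-based variance is then only within the
  interpolation error.
- Only uniform inputs are supported (Legendre basis, Clenshaw–Curtis
  rules); no Gaussian or arbitrary-distribution quadrature.
- Greedy variance-based refinement without exploration provably cannot
  discover directions in which the model coincides with its surrogate on
  every candidate grid; exploration mode mitigates but cannot certify
  coverage.
- The budget accounting assumes a sequential campaign; there is no
  parallel dispatch of ensemble members.
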