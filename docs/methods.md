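# Methods

## The model

A battery of D neurocognitive scores from N participants, z-scored per
measure, is modelled as a linear-Gaussian latent feature model

    X = Z A + E,   E_ij ~ Normal(0, sigma_x^2),

where Z is an N x K binary matrix (person i either samples feature k or
does not), and A is a K x D real matrix of feature-to-measure weights with
prior A_kj ~ Normal(0, sigma_a^2).  K is not fixed: Z carries an Indian
Buffet Process (IBP) prior with concentration `alpha`, under which the
expected number of features is `alpha * H_N` (H_N the N-th harmonic
number) and a feature sampled by m_k of the other people is sampled by a
new person with probability m_k / N.  Throughout the package `sigma_x` and
`sigma_a` are standard deviations.

Missing battery cells are handled exactly, never imputed: each cell
contributes a likelihood term only where observed, which under
missing-completely-at-random entries factorizes the collapsed likelihood
per measure,

    p(X_obs | Z) = prod_d  N(x_{O_d, d}; 0, sigma_x^2 I + sigma_a^2 Z_{O_d} Z_{O_d}^T),

with O_d the rows observed on measure d.

## Inference

The sampler is an accelerated (collapsed) Gibbs sampler: membership
entries z_ik are updated with the weights integrated out, using per-measure
stacks of G_d = Z_d^T Z_d + (sigma_x^2/sigma_a^2) I, their inverses and
h_d = Z_d^T x_d, maintained by rank-one identities as entries flip.  Each
update multiplies the prior odds m_{-i,k} / (N - m_{-i,k}) by the exact
Gaussian predictive of row i's observed cells.  Integrating the weights
matters: an explicit-weights scan is also implemented (`collapsed=False`)
and is exactly correct — it reproduces the enumerated posterior on tiny
instances — but its chains stall for tens of sweeps in local modes
("intercept plus complemented features", split features) because stale
weight draws lock memberships in place.

Per-row singleton features are removed and re-proposed each sweep from a
truncated Poisson(alpha/N) birth conditional (up to `k_cap = 4` new
features per row, new weights integrated against their prior).  Two
further moves improve mixing across modes, both exact
Metropolis–Hastings on the collapsed posterior:

- **Whole-feature birth/death.**  Entry-wise Gibbs can only grow a feature
  one member at a time, so a weak feature shared by many people is
  effectively unreachable — no single row justifies it alone.  A
  reversible pair of moves proposes an entire membership column at once
  (rows included with probability increasing in the cosine similarity of
  their current residuals to a uniformly chosen anchor row's residual,
  against posterior-mean weights) and deletes whole columns in reverse.
  Because the weights are integrated out the state is just Z and the
  acceptance ratio is an ordinary MH ratio; the proposal probability
  marginalizes the anchor choice.
- **Complement flips.**  When a near-universal feature exists (membership
  at least 85% of the sample), any other feature is proposed flipped to
  its complement; the near-universal feature's integrated weights absorb
  the constant shift.  This dismantles the classic intercept/complement
  local mode.

Hyperparameters: `alpha` has a Gamma(1, 1) prior and the conjugate update
alpha | K ~ Gamma(1 + K, 1 + H_N); it is initialized at 5 and held there
for the first 10 sweeps (warm-up) so that a chain started from an empty Z
is not starved of feature births before any structure exists.  The two
scales move by random-walk Metropolis on the log scale (proposal SD 0.1)
under Jeffreys 1/sigma priors, so the acceptance ratio reduces to the
Gaussian likelihood ratio of the observed-cell residuals (sigma_x) or the
weight entries (sigma_a).  After the membership scan, A is redrawn from
its exact Gaussian full conditional per measure, restricted to rows
observed on that measure (a measure observed nowhere falls back to the
prior); these draws feed the scale updates, the trace and all outputs.

Defaults: 50 sweeps (runs here converge within roughly 10–20; the margin
is deliberate), empty-Z initialization (a prior draw at alpha_init is
available), seed-deterministic throughout.  Convergence is reported, not
enforced, as the longest terminal window over which K and alpha (rounded
to 0.1) are constant.  Feature identity is not meaningful across runs
(label switching); all cross-run comparisons go through one-to-one
assignment matching on weight-vector cosine similarity.

## Continuous feature values

The per-person, per-feature quantity carried into the outcome analyses is
the full-conditional inclusion probability at the final state: prior odds
m_{-i,k} / (N - m_{-i,k}) times the likelihood ratio of row i's observed
cells under z_ik = 1 versus 0, evaluated at the final weights and scales.
A fully masked row receives exactly the prior m_{-i,k} / N; values lie in
[0, 1].  An alternative reading — averaging binary z over a terminal
window of sweeps — is available (`value_average_window`); the probability
reading is the default because it is the one the sampled state defines
per person without cross-sweep alignment.

## Preprocessing

Order: score-direction conventions (the three ANT efficiency scores are
negated so higher always means better), then the finger-tapping filter
(tap sums below 10 or above 151 are set missing; the boundaries are
retained), then per-column z-scoring over observed cells with sample SD
(n − 1).  Filtering precedes standardization so implausible tap counts
cannot contaminate column statistics; whether the original analysis used
this order is not documented, so the package records it as its own
choice.  Missingness is an explicit boolean mask end to end — no sentinel
values.

## Feature analysis

Features are retained when their final-iteration member count reaches
floor(fraction * N); the default fraction 0.05 reproduces the worked value
673 -> 33.  Profiles are per-measure means and standard errors of members'
z-scores over observed cells (SE undefined at one contributing cell,
reported as missing).  Demographic balance is tested member versus
non-member per retained feature: one-way ANOVA for age, chi-square
independence for sex and race/ethnicity; tests with empty expected cells
are skipped with a machine-readable warning.  Split-half stability halves
the sample with a seeded permutation, refits each half independently,
filters at the same fraction of the half size, and matches retained
features across halves by maximal total cosine similarity under a
one-to-one assignment.

## Correlation analysis

Feature values are Pearson-correlated with each outcome over jointly
observed pairs.  Differences between two features' correlations with the
same outcome are tested with overlapping dependent-correlation statistics;
the default is the Dunn–Clark/Steiger z on Fisher-transformed
correlations with the covariance term evaluated at the average of the two
overlapping correlations, with Williams' t and a Zou-style
confidence-interval method selectable.  Each comparison is computed on the
subsample jointly observed on both features and the outcome so the
correlation triple is internally consistent; inconsistent triples (a
non-positive-semidefinite 3 x 3 matrix) are rejected.  Bonferroni
correction multiplies p by the outcome-family size — 2 for the impulsive
behavior family and 4 for substance use by default — and never by the
number of feature pairs, which matches how the families are defined.

## Synthetic data

The generator plants a known model: independent Bernoulli memberships per
feature (popularity is controllable, unlike under the IBP prior, so filter
behavior is predictable), weights Normal(0, weight_scale^2) optionally
restricted to disjoint measure blocks for interpretable recovery, battery
X = Z A + noise with MCAR masking, and outcomes linear in the membership
indicators with coefficients solved so each outcome's population
correlation with each planted feature equals its target (unit outcome
variance; infeasible combinations raise).  Batteries can be emitted on an
arbitrary per-measure raw scale; z-scoring is affine-invariant, so this
exercises preprocessing without changing the fitted model.  Demographics
(age uniform on 18–55, configurable sex and race/ethnicity proportions)
are independent of the planted features by construction, which is what the
demographic-test calibration checks require.

What the generator does not emulate: real score distributions (skew,
floors and ceilings), not-at-random missingness, and correlated planted
features.  Passing recovery tests therefore show the machinery is correct
under its own assumptions, not that real batteries satisfy them.

## Verification choices and problem sizes

- The tiny-instance oracle enumerates all column multisets with at most 3
  features for N = 4, D = 2 (complete data, fixed hyperparameters) and
  compares the 50,000-sweep Gibbs distribution of K with the enumerated
  posterior by total variation; observed distances are around 0.01 against
  a 0.05 bar.
- The recovery study uses N = 300, D = 27, five disjoint block features,
  membership probability 0.3, noise SD 0.5, 5% missing cells, 50 sweeps,
  ten generator/sampler seed pairs.  Membership probability 0.3 is the
  package's choice of a realistic mid-popularity regime (expected ~90
  members, comfortably above the 5% filter at 15).
- With ~5 Normal(0, 1) loadings per block, occasional generator seeds
  produce a block with squared norm well below 1; for such features even
  the continuous values computed at the true parameters separate members
  from non-members with AUC below 0.9, so per-feature agreement above 0.9
  in nearly all runs is not attainable at these settings — the recovery
  report exposes this rather than hiding it.  Similarly, the posterior
  carries one or two transient small features at any sweep (the sweep
  after which K is recorded includes freshly born singletons), so the
  modal trace-tail K tends to sit one or two above the planted count even
  for long, verified-correct chains; the count of features surviving the
  5% filter is the quantity that recovers the planted K.
- The dependent-correlation calibration uses 5000 trivariate-normal
  replicates at n = 200; the power study uses 200 replicates at n = 600
  with ground-truth feature values so only the correlation stage is
  exercised.

## Numerical notes

- Collapsed-scan stacks are rebuilt from scratch at every sweep (and at
  every feature birth/death) to stop rank-one drift; downdates guard the
  leverage denominator at 1e-12.
- Logistic conditionals clamp |logit| at 35 before exponentiating.
- Degenerate inputs raise typed errors: zero-variance or under-observed
  battery columns, correlations on fewer than 3 joint pairs, |r| >= 1 or
  inconsistent correlation triples, infeasible outcome targets.
- Equal overlapping correlations short-circuit to statistic 0, p = 1,
  which also covers the identical-features case r_jk = 1.

## Limitations

- Single-chain inference; no cross-chain convergence statistics beyond the
  reported trace and terminal-stability window.
- The final-iteration state (not a posterior average) defines memberships
  and feature values, mirroring the analysis this package reimplements;
  results inherit that sweep-to-sweep variability.
- The collapsed scan's per-sweep cost grows with D distinct missingness
  patterns and K^2; it is comfortable at battery scale (hundreds of
  participants, tens of measures) but not tuned beyond it.
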