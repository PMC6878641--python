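# Methods

This note documents the models and procedures implemented in `spatialboot`,
the choices made where the design was genuinely open, and what the synthetic
experiments do and do not establish.

## Weight matrices

Inverse-distance weights are W_ij = 1/d_ij^alpha for i != j, zero diagonal.
Distances are Euclidean on the raw coordinates by default — for
longitude/latitude inputs this means degree-Euclidean distance, the
convention commonly applied to cluster GPS extracts; a haversine
great-circle mode (mean Earth radius 6371.0088 km) is available because
degree-Euclidean distorts over large extents.  The decay exponent defaults
to alpha = 1 (plain inverse distance), exposed everywhere as a parameter.

Zero distances between distinct units — the duplicated-GPS pathology that
motivates the whole package — are governed by an explicit `zero_policy`:
`error` (default; names the colliding units), `zero_weight` (drop the pair's
weight, used for the full-data reference matrix), or `epsilon` (substitute
1/epsilon^alpha).  Row standardisation divides each row by its sum; all-zero
rows are left untouched and counted in a diagnostic, since renormalising
them is undefined.

Storage is a dense array up to n = 2000 and scipy CSR above; row sums go
through one shared blockwise code path so the two representations agree
bit for bit.  Unit order (sorted cluster ids at the cluster level) is
recorded on the matrix, and all downstream vectors align to it.

## The one-per-cluster bootstrap

Every member of a cluster carries the cluster's coordinate, so any
subsample with exactly one member per cluster has the cluster-to-cluster
distance matrix — hence one weight matrix, built and row-standardised once,
serves every replicate (the test suite asserts entrywise equality across
100 random subsamples).  Replicate b draws one member uniformly per cluster
using the RNG stream keyed `(seed, b)` (a SeedSequence entropy pair rather
than arithmetic `seed + b`, so nearby base seeds do not share replicate
streams); the key is recorded per replicate so any single replicate can be
replayed.  Failed replicate fits are logged and skipped, with a hard error
if more than 10% fail.

Aggregation reports, per coefficient: the mean and SD of replicate point
estimates, the mean of replicate SEs (the two spread measures are reported
side by side because simulation tables are often ambiguous about which they
show), percentile 2.5/97.5 bootstrap interval bounds plus
normal-approximation bounds, coverage probability, and MSE.

- **Coverage probability** is the percentage of replicate-level 95% Wald
  (or posterior credible) intervals containing a fixed truth.  Values near
  95% indicate a reliable procedure.
- **MSE** is the mean of squared deviations of the replicate point
  estimates from the truth; the divisor is the number of replicate
  estimates (the quantity being averaged is indexed by replicate).
- **Truth** is the generating parameter vector when known (synthetic data,
  the default when the dataset carries a truth record), or a reference fit
  on the full original data, built with the `zero_weight` policy matrix,
  when requested via `truth="full_data_fit"`.

## Spatial lag model (ML)

y = rho W y + X beta + eps with eps ~ N(0, sigma^2 I) and W
row-standardised.  beta and sigma^2 are profiled out by least squares at
each rho; the concentrated log-likelihood adds the Jacobian
log|I - rho W| = sum_k log(1 - rho omega_k) from the (real) eigenvalues
omega of W, computed once and reusable across replicates that share W.  The
search interval is (1/omega_min + delta, 1/omega_max - delta) with
delta = 1e-6; estimates within 10*delta of an endpoint carry a boundary
warning.  Bounded scalar minimisation (xatol 1e-10) locates rho-hat; the
test suite checks it against an independent 1e-4-step grid search of the
same likelihood.  Standard errors come from the negative inverse of a
central-difference Hessian of the full log-likelihood in
(rho, beta, sigma^2); confidence intervals are Wald at 95% by default.
In the noiseless rho = 0 case sigma^2 collapses to zero; the profile
likelihood is floored rather than special-cased, the optimiser still drives
rho-hat below 1e-6 and the coefficients reduce to OLS (asserted to 1e-6).

## Spatial probit (Bayesian data augmentation)

For binary outcomes the latent index follows the spatial lag process,
z = rho W z + X beta + eps, eps ~ N(0, I), y_i = 1{z_i > 0}.  A Gibbs
sampler alternates (i) elementwise truncated-normal draws of z from the
full conditional with precision (I - rho W)'(I - rho W) — the precision
form avoids any per-iteration linear solve; (ii) conjugate normal beta
under a flat prior; (iii) griddy Gibbs for rho on a 0.005-step grid over
(-0.99, 0.99) with the eigenvalue log-determinant precomputed on the grid.
Defaults: 2000 kept draws after 500 burn-in; posterior means, SDs and
central 95% credible intervals are reported, and the draw sequence is a
pure function of the seed.  Pinning rho = 0 degenerates the sampler to the
classic augmented probit, which matches statsmodels ML probit within Monte
Carlo error (asserted at n = 500).  Within the bootstrap, replicates
default to 600 kept / 200 burn-in draws per fit to keep B replicates
affordable; this is a per-fit Monte Carlo error trade-off, configurable via
`probit_opts`.

## Moran's I

I = (n/S0) sum_ij W_ij z_i z_j / sum_i z_i^2 on mean-centred values, W as
given.  Normal-approximation inference uses the classic normality moments
(expectation -1/(n-1); variance from S0, S1, S2), two-sided p.  Permutation
inference permutes the values (two-sided pseudo p-value, floor
1/(n_perm+1)); under an i.i.d. null the permutation p-value is uniform
(Kolmogorov–Smirnov check in the suite).  For bootstrap summaries the CLI
reports the mean and SD of per-replicate statistics; no attempt is made to
attach a single p-value to an averaged bootstrap statistic, which has no
clean reference distribution.

## Synthetic surveys

The generator emulates the structure that matters: clusters placed
uniformly in a planar box with a minimum separation (default 100 clusters
in a 100×100 box, separation 1 — guaranteeing no zero cluster-to-cluster
distance), a fixed or range-valued number of members per cluster (default
20), every member stamped with the cluster's coordinates, and covariates
drawn per member (wealth: uniform integer quintile 1..5; education:
Poisson(6) years truncated to 0..20 — simple parametric stand-ins, since
real surveys' marginals are not the object of study).  An 850-cluster
preset mirrors the scale of a national survey.

Outcomes follow an individual-level spatial lag process whose weight matrix
block-expands the row-standardised cluster matrix: the weight from member j
(cluster c') to member i (cluster c != c') is Wc[c,c'] divided by the
member count of c', within-cluster weights zero.  Rows still sum to one and
the spatial term aggregates to cluster-mean outcomes, so a one-per-cluster
subsample follows the cluster-level spatial lag model up to within-cluster
sampling noise, making (rho_true, beta_true) a well-defined estimand for
the bootstrap; with equal cluster sizes the expanded matrix restricted to
any subsample is exactly proportional to the cluster matrix.  This is a
modelling choice that makes the estimand clean — not a claim about how real
surveyed populations generate outcomes.  Defaults for the reference
experiments: rho = 0.3, beta = (0.5, 0.2, 0.1) for (intercept, wealth,
education), noise SD 1, identity link.

The generator does not emulate GPS displacement/jittering, sampling
weights, or multi-stage design effects; passing tests therefore speak to
the procedure's behaviour under a clean spatial lag data-generating
process, not to those survey artefacts.

## Identification of rho under dense inverse-distance weights

A finding that shapes the experiment design: with alpha = 1 and units
spread over a uniform domain, the row-standardised inverse-distance W is
close to an averaging matrix — Wy is nearly collinear with the intercept —
and the ML spatial lag coefficient is only weakly identified (replicate SD
around 0.5 at n = 100–300; densification means more units do not help).
Two consequences:

- In the reference coverage study (alpha = 1, matching the conventional
  plain-inverse-distance choice), the covariate coefficients are well
  behaved — coverage ~94–95%, MSE near zero — while rho and the intercept,
  which absorbs rho's misestimation through the near-collinearity,
  undercover (~84–86%).  The reliability criterion is therefore evaluated
  on the covariate coefficients, which is also where substantive interest
  lies; the rho/intercept behaviour is reported, not hidden, and is a known
  limitation of inverse-distance spatial lags in the weak-autocorrelation
  regime.
- Parameter-recovery experiments use alpha = 3, a strongly localised weight
  structure under which rho is identified (replicate SD ~0.05 at n = 300);
  recovery cannot be demonstrated where the parameter is statistically
  unidentified.

## Problem sizes and numerical conventions

Reference experiment scales, chosen as desk-scale defaults: coverage study
20 outer repetitions × B = 500 bootstrap replicates on 100×20 surveys; lag
recovery 200 seeds at n = 300; probit recovery one n = 400 instance with
2000 kept draws; oracle equivalences at n ≤ 30.  CI level is 95%
throughout.  Eigenvalue-based log-determinants are supported to n = 3000;
beyond that a sparse/approximate determinant would be needed and is out of
scope.  Percentile bootstrap intervals use linear interpolation
(`numpy.percentile` default).  Ties in the uniform member draw are
impossible (continuous uniforms scaled to integer ranges with a top clamp).
Degenerate inputs fail loudly: constant outcomes for Moran's I, single-class
binary outcomes, rank-deficient designs (naming the collinear columns),
inconsistent within-cluster coordinates (naming the cluster), empty
clusters.

## Known limitations

- The intercept and rho of the spatial lag model are poorly determined
  under alpha = 1 inverse-distance weights (see above); interpret them with
  the reported uncertainty, which is honest but large.
- The spatial probit griddy-Gibbs resolves rho to the 0.005 grid step.
- No spatial error/SARAR models, ordered or multinomial outcomes, impact
  decompositions, BCa/studentized intervals, or k-NN/contiguity/kernel
  weights.
- The full-data reference fit with `zero_weight` duplicated-coordinate
  handling is one convention among several; it is exposed as a policy
  precisely because the right treatment is context-dependent.
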