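# spatialboot

Spatial regression on cluster-released survey data via a
one-observation-per-cluster bootstrap for inverse-distance weight matrices.

## The problem

Spatial econometric models need a spatial weight matrix **W**: an n×n
nonnegative matrix whose entry W<sub>ij</sub> encodes how strongly unit *j*
can influence unit *i*.  The inverse-distance form is

&nbsp;&nbsp;&nbsp;&nbsp;W<sub>ij</sub> = 1 / d<sub>ij</sub><sup>α</sup> for i ≠ j, and W<sub>ii</sub> = 0,

usually row-standardised so each row sums to one.  Large household health
surveys (DHS-style) release GPS coordinates only at the level of the primary
sampling unit ("cluster") to protect respondent confidentiality: every
participant in a cluster carries the cluster's single coordinate pair.  Two
consequences kill the direct construction: within-cluster distances are all
zero, so 1/d is undefined; and the full matrix (e.g. ~24,000×24,000 for a
national survey with 850 clusters) is unwieldy in standard tools.

The bootstrap procedure implemented here resolves both at once.  Each
replicate draws **one participant per cluster**, so all pairwise distances
are nonzero — and because those distances are cluster-to-cluster distances,
the weight matrix is *identical in every replicate*: it is the
inverse-distance matrix of the cluster centroids, built once and reused.
Fitting the spatial model on each replicate and aggregating over replicates
yields estimates, percentile confidence intervals, and reliability
diagnostics (coverage probability and mean squared error against a known or
reference truth).

## What is in the box

- `weights` — pairwise distances (planar, degree-Euclidean, great-circle),
  inverse-distance matrices with explicit zero-distance policies, row
  standardisation, the constant cluster-centroid matrix, MatrixMarket I/O.
- `moran` — global Moran's I with normal-approximation or permutation
  inference.
- `lag` — maximum-likelihood spatial lag regression
  y = ρWy + Xβ + ε, with the log-Jacobian log|I − ρW| = Σ<sub>k</sub> log(1 − ρω<sub>k</sub>)
  evaluated through the eigenvalues ω of W; OLS baseline; forward simulation
  from the spatial lag process.
- `probit` — Bayesian spatial-lag probit for binary outcomes (data
  augmentation: truncated-normal latents, conjugate β, griddy-Gibbs ρ).
- `bootstrap` — the one-per-cluster engine with coverage/MSE summaries.
- `synthetic` — generator for DHS-like clustered surveys with known spatial
  structure (duplicated within-cluster GPS included), so everything is
  testable without restricted data.
- `cli` — `spatialboot simulate | build-weights | moran | fit-lag |
  fit-probit | bootstrap`.

The modelling surface follows the statsmodels idiom: model objects
(`SpatialLag`, `SpatialProbit`, `OnePerClusterBootstrap`) are built from
data and their `fit()` / `run()` return results objects with estimates,
uncertainties and a `summary()`.

## Worked example

```python
import spatialboot as sb

cfg = sb.SyntheticConfig(n_clusters=100, members_per_cluster=20,
                         rho_true=0.3,
                         beta_true={"Intercept": 0.5, "wealth": 0.2,
                                    "education": 0.1},
                         noise_sd=1.0, seed=1)
survey, truth = sb.generate_survey(cfg)

W = sb.row_normalize(sb.cluster_centroid_matrix(survey))
vals = (survey.df.groupby("cluster_id")["outcome"].mean()
        .reindex(W.unit_order).to_numpy())
m = sb.morans_i(vals, W)
print(f"Moran's I = {m.I:.4f} (expected {m.expected:.4f}, p = {m.p_value:.3f})")

boot = sb.OnePerClusterBootstrap(survey, model="lag_ols",
                                 formula="outcome ~ wealth + education")
print(boot.run(B=1000, seed=2).summary())
```

prints

```
Moran's I = 0.0022 (expected -0.0101, p = 0.449)
One-per-cluster bootstrap: model=lag_ols B=1000 failed=0 seed=2 CI level=95%
           mean_est    sd_est   mean_se    ci_low   ci_high  norm_ci_low  norm_ci_high  coverage_pct       mse  truth_used
rho       -0.370725  0.528881  0.540623 -1.513097  0.464869    -1.407313      0.665863     84.100000  0.729307    0.300000
Intercept  2.099743  1.321872  1.361746 -0.002881  4.958177    -0.491079      4.690566     85.500000  4.304778    0.500000
wealth     0.189597  0.069424  0.069983  0.059382  0.327222     0.053528      0.325666     95.100000  0.004923    0.200000
education  0.109517  0.037765  0.039491  0.037187  0.182796     0.035498      0.183536     95.500000  0.001515    0.100000
```

Reading it: Moran's I of the cluster-mean outcomes is near its null
expectation −1/(n−1) — weak spatial autocorrelation, the regime this kind of
survey typically sits in.  Each bootstrap row aggregates 1,000 replicate
fits: the covariate coefficients (wealth 0.19 vs generating 0.2, education
0.11 vs 0.1) are recovered with per-replicate 95% CIs covering the truth
about 95% of the time and MSEs near zero.  The spatial lag coefficient ρ and
the intercept are far noisier: with inverse-distance weights at α = 1, Wy is
nearly collinear with the intercept, so ρ is only weakly identified and the
intercept absorbs its misestimation (see `docs/methods.md`).  The same
workflow runs from the shell: `spatialboot simulate`, then
`spatialboot bootstrap --input survey.csv --truth-json truth.json`.

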