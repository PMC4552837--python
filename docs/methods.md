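# Methods

## Model

Presence `Y_t(s) ∈ {0,1}` of the target species at site `s` during
deployment `t` follows a Bernoulli law with

    logit p_t(s) = X_t(s) β + η(s)

`X_t(s)` is a 10-column design vector in fixed order: intercept, two
protection-status dummies (`green_old`, `green_new`; baseline `open`),
standardized depth, four binary habitat indicators (`rock`, `kelp`, `sand`,
`coffee_rock`; present at ≥5% cover), a winter dummy (baseline summer), and
standardized visibility. Status, season and visibility may vary across
repeat deployments of a site; depth and habitat are site properties.

`η` is a zero-mean stationary isotropic Gaussian process over planar UTM
coordinates with exponential covariance

    Cov(η(s_i), η(s_j)) = σ² exp(−φ ‖s_i − s_j‖),   distances in meters.

Sites are distinct exactly when their coordinates differ; repeat
deployments of one site share one `η(s)`. The model assumes no residual
temporal structure beyond the season/status/visibility covariates — a
reasonable simplification for a study window of a few years — and isotropy,
which a linear-coastline sampling design could not distinguish from mild
anisotropy anyway. The non-spatial model omits `η` entirely.

### Priors

- `β_i ~ N(0, 2.5)` independently. The dispersion 2.5 is read as a
  **variance** (sd ≈ 1.58); on the probability scale this spreads prior
  presence probabilities roughly uniformly over (0,1). `PriorSpec`
  exposes `beta_scale_is_variance=False` to read the same number as a
  standard deviation, since weakly-informative-logistic-prior conventions
  differ on this point.
- `1/φ ~ Uniform(50, 1500)` meters. σ² and φ are only jointly identified
  from binary data, so the decay gets the informative prior: the induced
  effective range `3/φ` spans 150–4500 m, sensible for sites tens of
  meters to tens of kilometers apart.
- `σ² ~ InvGamma(shape 2, scale 2)` (mean 2, infinite variance): broad on
  the spatial variance. Shape/scale parameterization, density
  `∝ x^{−a−1} e^{−b/x}`.

The *effective range*, the distance at which correlation decays to 0.05,
is `−log(0.05)/φ ≈ 3/φ`.

## Sampler

Both models are fitted by Markov chain Monte Carlo using Pólya-Gamma data
augmentation: introducing `ω_i ~ PG(1, x_i'β + η_i)` renders the Bernoulli
likelihood conditionally Gaussian in the linear predictor, giving exact
conjugate multivariate-normal updates for `β` and `η`, a conjugate
inverse-gamma update for `σ² | η, φ`, and leaving only `φ` to a
random-walk Metropolis step on the logit-transformed inverse decay within
its uniform bounds (with the Jacobian included). The augmented chain
targets the stated posterior exactly; the augmentation is an algorithmic
device, not a model change.

**PG(1, z) draws** use the weighted-sum-of-exponentials representation

    PG(1, z) = (1/2π²) Σ_{k≥1} E_k / ((k − ½)² + z²/4π²),  E_k ~ Exp(1),

truncated at 200 terms with the exact mean of the dropped tail added as a
deterministic top-up. The draw's mean is exact for every `z`; only O(1/200)
of the variance is replaced by its expectation. Tests validate the draws
against the closed-form PG mean and variance, and the sampler as a whole
against a brute-force grid-integration posterior (total variation < 0.05).

**Proposal adaptation.** The `1/φ` random-walk scale is tuned during
burn-in only (multiplicative updates every 50 iterations toward ~35%
acceptance) and frozen afterwards, preserving the stationary target.

**Numerics.** Site covariance factorizations add a relative diagonal
jitter (default 1e-8 of σ²). `fit_model` refuses single-class responses
(complete separation). `FitConfig.fix_sigma2` / `fix_phi` pin those
parameters, used to verify that the spatial model collapses onto the
non-spatial one as σ² → 0. Defaults follow the convention of 5000 retained
draws after 1000 burn-in iterations, thinning every 2nd iterate
(non-spatial) or 10th (spatial); tests and the acceptance script use
smaller chains (200–4000 retained) chosen so that Monte Carlo error is
well below the effect sizes being checked.

## Evaluation

Per retained draw `m`, predicted probabilities are
`p^(m) = logit⁻¹(X β^(m) + η^(m))`. Metrics per draw: log-likelihood
`Σ[y log p + (1−y) log(1−p)]` (probabilities clipped at 1e-12), MSE
`mean (y − p)²`, and ROC AUC (Mann–Whitney form, ties ½ — identical to
trapezoidal ROC integration; computed by scikit-learn and cross-checked in
tests against exhaustive pairwise concordance). Summaries are the
posterior mean and a central 95% interval.

**Interval convention.** Central intervals use outward-rounded order
statistics at Weibull plotting positions `(k+1)/(n+1)`: the endpoints are
the outermost order statistics whose expected CDF position lies outside
[α/2, 1−α/2]. This is conservative for short chains (expected coverage
never below nominal, so intervals from a thinned chain widen rather than
shrink on average) and converges to ordinary empirical quantiles. HPD
intervals (used for the skewed effective-range posterior) are the shortest
contiguous window of the sorted sample containing `⌈level·n⌉` points; by
construction never wider than the central interval at the same level.

**Cross-validation** blocks by location: sites are dealt into k near-equal
folds from a seeded permutation, and every observation inherits its site's
fold, preventing leakage through repeat deployments. Each fold's models
are fitted on the complementary folds only; held-out covariates are
standardized with the training constants. For the spatial model the latent
effect at held-out sites is **sampled** per posterior draw from its
conditional Gaussian given that draw's `(η_train, σ², φ)` — mean
`c'C⁻¹η`, covariance `σ²Σ_new − c'C⁻¹c` — because a new site's effect is
itself uncertain; a plug-in conditional-mean mode exists for diagnostics.
Out-of-sample LL/MSE/AUC are posterior means over draws, reported per fold
plus the across-fold mean.

**Odds ratios.** Point estimate: posterior mean of `exp(β)`; interval:
`exp` of the β interval endpoints (quantile equivariance). `exp(E[β])` is
reported alongside since the two conventions diverge for skewed
posteriors (Jensen: `E[exp β] ≥ exp(E β)`).

**Spatial-effect surfaces** evaluate, at each grid-cell center, the
posterior mean over draws of the kriged conditional mean of `η` (which is
σ²-free). Cells farther than a cutoff — default the posterior-median
effective range — from every site are masked, because beyond it the
conditional mean reverts to ~0 and mapping it would be misleading. An
alternative (binning site-level posterior means per cell) was considered
and not used; kriging gives the model-consistent interpolant.

## Synthetic surveys

The generator emulates the sampled structure of a clustered coastal BUV
program; defaults target the emulated study's scale:

| parameter | default | meaning |
|---|---|---|
| clusters × sites | 6 × 29 = 174 | sites in a 30 km × 3 km band |
| cluster_spread | 600 m | site scatter around cluster centers |
| min_site_distance | 20 m | enforced by rejection (1000 retries, then error) |
| revisit_probability | 0.52 | per extra time point; 5 seasonal time points → ~536 deployments |
| habitat prevalences | rock .35, kelp .20, sand .50, coffee .25 | marginal site frequencies |
| habitat_clump_range | 500 m | effective range of the thresholded habitat GPs |
| beta_true | (−1.3, −0.40, −0.12, 0.28, 0.54, 2.30, −0.01, 1.16, 0.64, 0.31) | logit scale, design-column order |
| sigma2_true, phi_true | 1.0, 3/2000 | GP variance; effective range 2000 m |

Habitat indicators come from thresholding independent unit-variance GPs at
the normal quantile of each prevalence, giving spatially clumped mosaics
with exact marginal prevalence. Protection zones are axis-aligned
rectangles along the band; "new" zones switch from open to no-take at the
third of five time points, making status time-varying as in a real
re-zoning. Depth increases across the band (offshore gradient) with local
relief; visibility is lognormal per deployment. `beta_true` defaults sit
in the regime of the non-spatial fit to real BUV data (strong kelp and
coffee-rock effects, weak status effects) so recovery tests operate at
realistic signal strength.

What the generator does **not** emulate: spatially balanced (GRTS-style)
site selection, the real habitat mosaic's cross-correlations (e.g.,
kelp–rock association), depth-dependent detectability, tides/currents, and
count-valued responses. Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions —
not robustness to the ways real surveys violate them.

## Validation summary

The test suite checks, among others: exact-arithmetic oracles for
standardization, likelihood values, AUC and kriging moments; distributional
oracles for the PG sampler and GP draws; a grid-integration oracle for the
full posterior on a toy dataset; β interval coverage and factor-2
effective-range recovery over 20 replicate surveys at 150 sites; the
σ² → 0 nesting property; and determinism of every seeded path. The
reproduction pipeline for the published processed survey table
(`reproduce_study`) is implemented and tested, but the table itself is
journal supplementary material the user must supply at
`data/moreton_bay_buv.csv`; without it that single test fails by design.

## Known limitations

- The exponential kernel and isotropy are fixed; no Matérn family or
  anisotropy.
- σ² and φ remain weakly identified from binary data; interpret their
  marginals (and the effective range) with the joint posterior in mind.
- Metropolis on φ with a per-iteration Cholesky is O(S³); fine for a few
  hundred sites, not for thousands.
- Kriged surfaces and predictions condition on training-site effects only;
  no observation-level nugget is modelled.
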