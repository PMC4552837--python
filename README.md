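# buvspatial

Bayesian spatial presence–absence modelling for baited-underwater-video
(BUV) surveys.

## The problem

BUV monitoring programs deploy baited camera rigs at clustered coastal
sites — often inside and around marine no-take ("green") zones — and record
whether a target fish species appears during each deployment. The standard
analysis treats deployments as independent given the measured covariates
(depth, season, visibility, habitat type, protection status). But sites sit
tens of meters to a few kilometers apart, and unmeasured micro-habitat
features induce spatial dependence that, left unmodelled, can bias effect
estimates and overstate confidence.

`buvspatial` is for ecologists and biostatisticians analysing such
presence–absence survey tables. It fits and compares two Bayesian logistic
regressions:

- **Non-spatial model**: `logit p_t(s) = X_t(s) β`
- **Spatial model**: `logit p_t(s) = X_t(s) β + η(s)`, where `η` is a
  zero-mean Gaussian process over site coordinates with exponential
  covariance `Cov(η(s_i), η(s_j)) = σ² exp(−φ‖s_i − s_j‖)` (planar meters).

Priors: `β_i ~ N(0, 2.5)` (variance 2.5, configurable), `1/φ ~ Unif(50,
1500)` m, `σ² ~ InvGamma(2, 2)`. The *effective range* — the distance at
which spatial correlation falls to 0.05 — is `3/φ` for this kernel.

Inference is by Pólya-Gamma-augmented Gibbs sampling (exact conjugate
updates for β, η and σ²; random-walk Metropolis on the transformed inverse
decay `1/φ`). Models are compared by posterior log-likelihood, MSE and ROC
AUC, both within-sample and under **location-blocked k-fold
cross-validation**, where every repeat deployment of a site shares the
site's fold and the spatial effect at held-out sites is drawn from its
conditional Gaussian (kriging) per posterior sample.

A synthetic-survey generator reproduces the statistical structure of a real
monitoring design (clustered sites in an elongated coastal band, a minimum
inter-site distance, seasonal revisits, mid-study zone closures, spatially
clumped habitat) so the whole pipeline is testable end to end.

## Worked example

```python
import buvspatial as bv

config = bv.SimulationConfig(seed=7)      # 174 sites, ~540 deployments
data, truth = bv.simulate_survey(config)

priors = bv.PriorSpec()
spatial = bv.fit_model(data, priors, bv.FitConfig(
    spatial=True, n_retained=1000, burn_in=500, thin=2, seed=0))

for s in bv.summarize_coefficients(spatial):
    flag = "*" if s.significant else " "
    print(f"{s.name:12s} {s.posterior_mean:6.2f} "
          f"({s.ci_low:6.2f}, {s.ci_high:6.2f}){flag}  OR {s.or_mean:5.2f}")

er = bv.effective_range_summary(spatial)
print(f"effective range: median {er['median']:.0f} m, "
      f"95% HPD ({er['hpd_low']:.0f}, {er['hpd_high']:.0f})")
```

prints

```
intercept     -1.73 ( -2.51,  -1.00)*  OR  0.19
green_old     -0.98 ( -2.11,   0.12)   OR  0.44
green_new     -0.27 ( -1.01,   0.54)   OR  0.82
depth          0.07 ( -0.32,   0.41)   OR  1.09
rock           0.44 ( -0.29,   1.21)   OR  1.66
kelp           2.06 (  1.28,   2.89)*  OR  8.48
sand          -0.04 ( -0.62,   0.54)   OR  1.01
coffee_rock    1.76 (  1.11,   2.41)*  OR  6.16
winter         0.66 (  0.21,   1.11)*  OR  1.98
effective range: median 1155 m, 95% HPD (153, 2535)
```

Each row is a coefficient's posterior mean, central 95% credible interval
(`*` when it excludes zero) and the posterior-mean odds ratio `E[exp β]`.
Here the survey was simulated with strong kelp and coffee-rock effects
(true log-odds 2.30 and 1.16) and a GP effective range of 2000 m; the fit
recovers the habitat effects, flags the null sand effect as insignificant,
and places the effective range's HPD interval around the truth. The kelp
odds ratio of 8.5 reads: the odds of observing the species are ~8.5 times higher
where kelp covers at least 5% of the site, all else equal.

Within-sample comparison and blocked cross-validation:

```python
P = bv.predict_probabilities(spatial, data)
summ = bv.metric_summaries(data.presence, P)     # LL, MSE, AUC summaries
cv = bv.cross_validate(data, priors, bv.FitConfig(
    spatial=True, n_retained=500, burn_in=300, thin=2), k=5, seed=1)
print(cv.table)                                  # per-fold + mean rows
```

A command-line pipeline mirrors the library:

```bash
buvspatial simulate --config config.yaml --out data.csv
buvspatial fit --data data.csv --model spatial --out draws.tsv
buvspatial evaluate --draws draws.tsv --data data.csv --out metrics.tsv
buvspatial cv --data data.csv --k 5 --seed 1 --out cv.tsv
buvspatial report --draws draws.tsv --out-coefficients coef.tsv \
    --surface-cell 500 --out-surface surface.asc
```

`report --surface-cell` rasterizes the posterior-mean spatial effect on
square grid cells (masked beyond the posterior-median effective range from
any site) as a plain ASCII grid.

## Analysing your own survey

`bv.load_survey_csv(path)` reads a per-deployment CSV with columns
`site_id, easting, northing, season, status, depth, visibility, rock, kelp,
sand, coffee_rock, presence` (UTM meters; `status` in
`open/green_old/green_new`; `season` in `winter/summer`; habitat indicators
0/1 at a ≥5% cover threshold). `bv.reproduce_study(path)` runs the complete
analysis — summary proportions, both fits, odds ratios, effective range,
within-sample metrics and 5-fold blocked CV — in one call.

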