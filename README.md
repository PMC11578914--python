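# ordinvar

Ordinal multigroup confirmatory factor analysis, measurement-invariance
testing and latent-mean trend estimation — for researchers who need to know
whether a change in survey symptom scores across cohorts is real latent
change or an artifact of changed item functioning.

Repeated cross-sectional surveys (new respondents each year, same
instrument) are the backbone of adolescent mental-health trend research.
Comparing mean scores across years, genders or age bands silently assumes
the instrument measures the same construct the same way in every group.
`ordinvar` makes that assumption testable for short ordinal scales and
quantifies what happens to the trend when it fails.

## The model

Each of K ordinal items (categories 1..C) is a thresholded latent response
variate under a one-factor normal-ogive model: for item j in group g,

```
y*_j = nu_jg + lambda_jg * eta + eps_j        eta ~ N(kappa_g, phi_g)
Y_j  = c  iff  tau_{j,c-1,g} < y*_j <= tau_{j,c,g}
```

with correlated residuals for declared item pairs and delta
parameterization (reference group standardized).  The model is fitted by
diagonally weighted least squares to the polychoric moment vector
(thresholds + correlations), with a mean-and-variance-adjusted test
statistic and sandwich standard errors — the combination commonly labelled
WLSMV.  On top of that sit:

* the **invariance ladder** configural → equal thresholds → equal loadings →
  equal intercepts, judged by ΔRMSEA ≤ 0.01 ∧ ΔCFI ≥ −0.004 (thresholds,
  loadings) and the stricter ΔCFI ≥ −0.002 (intercepts), with a greedy
  refit-based partial-invariance search budgeted at half the items;
* **d_MACS** effect sizes of item noninvariance on the observed-score scale;
* **latent-mean trends** as standardized deviations from a reference group,
  with delta-method CIs, plus the freed-vs-fixed counterfactual that shows
  how much detected noninvariance actually distorts the trend;
* **parallel analysis** (200 margin-preserving reference datasets, 95th
  percentiles) and the first/second-eigenvalue-ratio > 4 rule;
* **dynamic fit-index cutoffs** simulated from the fitted model at graded
  misspecification levels;
* a **synthetic survey generator** with controllable noninvariance, so every
  stage is testable without access to restricted survey data.

## Worked example

Inject intercept drift on item 6 in the two most recent of four cohorts,
then let the ladder find it:

```python
from ordinvar import (build_spec, inject_noninvariance, simulate_dataset,
                      run_ladder, latent_trend)

spec = build_spec(n_groups=4, n_per_group=2000, missing_rate=0.055)
spec = inject_noninvariance(spec, item=5, parameter="intercept",
                            shift=0.5, target_groups=["g3", "g4"])
data = simulate_dataset(spec, seed=1)

result = run_ladder(data, resid_pairs=[(2, 3)])
print(result.summary_table().round(4).to_string(index=False))
print("achieved:", result.achieved, "| freed:", result.freed)
```

```
     model    chi2  df    cfi  rmsea  rmsea_lo  rmsea_hi    tli   srmr    dcfi  drmsea decision
configural 31.2353  32 1.0000 0.0000       0.0    0.0160 1.0000 0.0104     NaN     NaN
thresholds 52.2373  50 0.9999 0.0047       0.0    0.0154 0.9999 0.0104 -0.0001  0.0047     pass
  loadings 84.5283  65 0.9995 0.0123       0.0    0.0191 0.9996 0.0124 -0.0004  0.0075     pass
    scalar 96.8562  77 0.9995 0.0114       0.0    0.0179 0.9996 0.0127 -0.0000 -0.0009     pass
achieved: partial-scalar | freed: {'thresholds': [], 'loadings': [], 'intercepts': [5]}
```

The scalar step initially fails the ΔCFI ≥ −0.002 rule; the partial search
frees exactly the injected item (item 6, index 5), after which the partial
scalar model passes (the table shows the accepted partial fit, df = 77
instead of 80).  Latent means are now comparable:

```python
print(latent_trend(result, "g1").to_frame().round(3).to_string(index=False))
```

```
group  deviation    se  ci_lower  ci_upper reference        variant
   g1      0.000 0.000     0.000     0.000        g1 partial scalar
   g2     -0.023 0.036    -0.095     0.048        g1 partial scalar
   g3     -0.043 0.037    -0.116     0.030        g1 partial scalar
   g4     -0.037 0.037    -0.109     0.035        g1 partial scalar
```

All four cohorts share the same latent mean in this DGP, and the estimated
standardized deviations are within sampling error of zero — the 0.5-SD-sized
intercept drift on one item was caught and quarantined instead of leaking
into the trend.

A CLI wraps the same stages (`ordinvar simulate / check-dim / invariance /
trends / dmacs / dfi / run-all`); `run-all` writes a JSON manifest plus
delimited tables that reproduce bit-identically under a fixed config + seed.

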