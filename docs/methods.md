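# Methods

## Problem and model

Repeated cross-sectional surveys often show rising adolescent symptom
scores, and the standing question is whether such trends reflect real change
in the latent construct or a drift in how respondents interpret and endorse
the items (measurement noninvariance).  `ordinvar` implements the full
psychometric chain needed to answer that question for a short ordinal scale:
dimensionality checking, ordinal multigroup CFA, a sequential invariance
ladder, effect sizes of noninvariance, and latent-mean trend estimation with
a freed-vs-fixed counterfactual.

The measurement model is a one-factor normal-ogive model.  For item
j = 1..K (default K = 6) in group g, a latent response variate

    y*_jg = nu_jg + lambda_jg * eta + eps_jg,      eta ~ N(kappa_g, phi_g)

is cut into C ordered categories (default C = 4) by thresholds tau_jcg;
residuals eps are multivariate normal with variances theta_jg and
correlations for declared item pairs (default: items 3 and 4, reflecting
overlapping content).  Under the delta parameterization the model is scaled
through the total y* standard deviation (`sd_jg`); the reference group is
standardized (sd = 1, kappa = 0, phi = 1).

## Estimation

Estimation is the standard three-stage ordinal-SEM pipeline, written here
from first principles:

1. **Thresholds** per item and group: tau_c = Phi^-1(cumulative proportion),
   from all available cases of that item (pairwise deletion throughout).
2. **Polychoric correlations** per item pair: two-step maximum likelihood —
   thresholds fixed at step-1 values, the one-parameter bivariate-normal
   multinomial likelihood maximized by bracketed root finding of its
   analytic score on (-0.999, 0.999) (vectorized bisection over all pairs;
   interval width < 1e-12 at termination).  Boundary solutions are clipped
   with a warning.  Bivariate normal rectangle probabilities come from a
   vectorized Genz/Drezner–Wesolowsky routine accurate to ~1e-14.
3. **DWLS fit**: the model-implied thresholds and correlations sigma(p) are
   fitted to the stacked sample vector s by minimizing
   F = sum_g (n_g/N) (s_g - sigma_g)' W_g^-1 (s_g - sigma_g) with diagonal
   W_g, via L-BFGS-B with analytic Jacobians (convergence: max |gradient|
   < 1e-4, typically < 1e-7; a gradient above 1e-2 raises a convergence
   error).  Inadmissible regions (theta <= 0) are excluded by a quadratic
   penalty; solutions at the boundary are flagged as Heywood cases.

The asymptotic covariance Gamma_g of the sample statistics is assembled from
analytic influence functions: the threshold influence is the classic
indicator form, and the polychoric influence corrects the pairwise score for
the estimated thresholds (A^-1 [score + b' psi_tau] with A the pairwise
information and b the cross-derivative of the score in the thresholds).
Pairwise-deleted statistics rescale their influence by n/n_available, which
is consistent under MCAR and the usual pragmatic choice under mild MAR.

The reported test statistic is the mean-and-variance-adjusted
(scaled-and-shifted) form a*T + b with T = N*F_min, a = sqrt(df/tr(M^2)),
b = df - a*tr(M), M = U Gamma*, computed from block/low-rank trace
identities.  Standard errors are sandwich estimates.  In simulation at the
package's default conditions the scaled statistic is calibrated at every
invariance level (mean ~ df, SD ~ sqrt(2 df)).

Fit indices use the scaled statistic: CFI and TLI against a free-threshold,
zero-correlation baseline with max(., 0) guards; multigroup RMSEA multiplies
the per-group noncentrality form by sqrt(G), with N - G in the denominator
and a 90% CI from noncentral chi-square inversion; SRMR is the RMS of
residual polychoric correlations (thresholds excluded).

## Identification schedule of the invariance ladder

Ordinal invariance testing needs an explicit identification schedule because
the latent response scale is indeterminate.  The schedule used here, one
concrete realization of the threshold → loading → intercept sequence:

| level      | tau    | lambda | nu (non-ref)  | sd (non-ref) | phi (non-ref) | kappa (non-ref) |
|------------|--------|--------|---------------|--------------|---------------|-----------------|
| configural | free/g | free/g | 0             | 1            | 1             | 0               |
| thresholds | equal  | free/g | free          | free         | 1             | 0               |
| loadings   | equal  | equal  | free          | free         | free          | 0               |
| scalar     | equal  | equal  | 0 (equal)     | free         | free          | free            |

With C = 4, equating the three thresholds of an item across groups frees
that item's nu and sd in non-reference groups with one df to spare per item,
which is what makes the threshold step testable.  A partially freed item
reverts to configural-style identification (thresholds free per group,
nu = 0, sd = 1) for that item.

Degrees-of-freedom bookkeeping for G groups, K = 6, C = 4: the threshold
step adds 6(G-1) constraints, the loading and intercept steps 5(G-1) each.

## Decision rules

Nested transitions are judged by delta fit indices, never the chi-square
difference (meaningless at survey sample sizes):

* thresholds and loadings: pass iff ΔRMSEA <= 0.01 **and** ΔCFI >= -0.004;
* intercepts: pass iff ΔCFI >= -0.002 (stricter, because missing
  consequential noninvariance is the costlier error).

On failure, a greedy refit-based partial search frees one item at a time —
the item whose release gives the restricted model the highest CFI, ties
broken by item index — until the rule passes or more than half the items
(3 of 6) would be freed, which is declared noninvariance.  The search is
refit-based (never approximation-based), so freeing a parameter cannot lower
the restricted model's CFI.  Every decision stores its Δ values and is
bit-exactly reproducible from the audit trail.

A caveat worth knowing: DIF is only identified relative to a majority of
invariant items.  If a majority of items shift *uniformly*, the model cannot
distinguish that from a latent-mean difference plus DIF on the complement,
and the search will legitimately free the complement.  The budget-exhaustion
path therefore only triggers for shift patterns that no within-budget
representation can absorb (e.g. shifts of mixed sign).

## d_MACS

For item-level magnitude of noninvariance,

    d = sqrt( int (E_F[Y|eta] - E_R[Y|eta])^2 N(eta; kappa_R, phi_R) deta ) / SD_pool

by Gauss–Hermite quadrature (50 nodes; convergence verified by node
doubling, |Δd| < 1e-4).  The pooled SD is the root mean of the two groups'
model-implied observed item variances, each under its own latent
distribution (the cited definition leaves the denominator open; this choice
is pinned here).  Bands: < 0.20 negligible, 0.20–0.40 small, 0.40–0.70
medium, >= 0.70 large.  The measure is asymmetric in the reference choice by
construction — the reference latent distribution weights the integral — and
the package does not "fix" that.

## Trends

Latent means are only reported at (partial) scalar invariance.  Trends are
standardized deviations (kappa_g - kappa_ref)/sqrt(phi_ref) — the reference
group's latent SD, not a pooled one — with delta-method 95% CIs from the
sandwich covariance.  The freed-vs-fixed comparison refits the scalar model
with and without the flagged intercepts freed and reports per-group trend
differences and their maximum; this is the practical-significance check.
The one-way ANOVA ICC (truncated at zero) quantifies clustering of observed
item scores when cluster IDs are present.

## Parallel analysis

Observed eigenvalues of the (default polychoric) item correlation matrix
against the 95th percentile of eigenvalues from 200 reference datasets.  The
default reference scheme permutes each observed column independently, which
preserves the ordinal margins exactly; an independent-multinomial scheme is
switchable.  Components are retained sequentially while observed > reference
percentile.  The first/second eigenvalue ratio > 4 flags essential
unidimensionality.  Whether polychoric or Pearson correlations feed the
eigendecomposition is configurable and recorded in the report.

## Dynamic fit-index cutoffs

Level 0 simulates from the fitted model; Level k adds k omitted residual
correlations of 0.3 at the lowest-index unmodeled pairs.  Cutoffs are the
5th percentile of CFI and 95th of RMSEA/SRMR across replications (default
200; reduced desk modes documented per run).  Because the ladder is nested,
cutoffs are isotonized across levels (running max for RMSEA/SRMR, running
min for CFI) so the acceptance regions nest; raw percentiles and an
adjustment flag are kept in the output.  This matters because a one-factor
model absorbs part of a second omitted correlation by inflating loadings,
leaving Levels 1 and 2 close enough for raw percentiles to cross by Monte
Carlo noise.  Each index self-accepts at 95% by construction; the joint
three-index Level-0 acceptance is necessarily somewhat below 95% because the
indices are only partially dependent (measured ~0.90–0.95).

## Synthetic data generator

The generator emulates the target survey's design: K = 6 items on a 4-point
scale, loadings 0.65–0.86 (defaults 0.80, 0.70, 0.86, 0.83, 0.65, 0.75),
right-skewed thresholds (most mass in the low categories, as in symptom
data), a 0.25 residual correlation between items 3 and 4, group grids up to
10 years x 2 genders x 5 age bands with n = 600–6000 per group, and 5.5%
item-level MCAR missingness (an optional MAR mode, missingness increasing in
the trait with a logistic link calibrated to the marginal rate, is off by
default).  Noninvariance is injected surgically per item/parameter/group
set, with provenance recorded in the spec; an intercept shift on y* and an
opposite uniform threshold shift are equivalent entry points.  One root seed
spawns an independent substream per group (keyed by group position), so
adding a group never perturbs the others, and identical spec + seed is
bit-identical.

What the generator does *not* emulate: municipality sampling frames and
privacy suppression, item wording or order effects (e.g. reversed response
options in a specific survey year), non-normal latent distributions, and
informative missingness tied to observed covariates.  Passing the package's
simulation checks therefore demonstrates correctness of the machinery under
the stated model, not robustness to those real-data complications.

## Desk-scale study sizes

The validation studies (`ordinvar.validation`, also driven by
`scripts/acceptance.py`) run at desk scale chosen to keep a full pass in
minutes on one CPU: ladder operating characteristics at 6 groups x n = 2000
with ~100 replications; DIF detection at 4 groups with 100 replications;
trend CI coverage at 200 replications; freed-vs-fixed drift at 10 cohorts
with ~60 replications and age-style bias at 5 groups with ~40; parallel
analysis over 20 seeds x 200 reference sets; DFI at 150 replications per
level.  Rates at these scales carry binomial Monte-Carlo error of a few
percentage points.

Known limitations: one factor only (no hierarchical or multi-factor
structure), delta parameterization only, no full-information ML, no
alignment or Bayesian approximate-invariance alternatives, and no
age–period–cohort decomposition.  The ΔRMSEA <= 0.01 rule is noticeably
noisy with few groups (at G = 4, n = 2000 it false-fails a correct loading
step in roughly one run in ten purely through RMSEA sampling noise, a known
property of RMSEA-difference rules calibrated for many-group settings);
with 6–10 groups the ladder's overall false-failure rate is well under 10%.
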