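"""Latent-mean trends across cohorts and their sensitivity to noninvariance.

Once (partial) scalar invariance holds, group latent means are comparable.
Trends are reported as standardized deviations from a chosen reference group,

    (kappa_g - kappa_ref) / sqrt(phi_ref),

with delta-method 95% confidence intervals from the sandwich parameter
covariance.  The freed-vs-fixed comparison refits the scalar model with and
without the designated noninvariant parameters freed and reports how much
the trend estimates move — the practical-significance check for whether
noninvariance distorts cross-cohort comparisons.  A one-way random-effects
ICC quantifies clustering of observed item scores (e.g. by municipality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import OrdinalFactorModel, OrdinalFactorResults

__all__ = [
    "TrendResult",
    "latent_trend",
    "freed_vs_fixed",
    "icc_oneway",
    "descriptives",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class TrendResult:
    """Standardized latent-mean deviations from a reference group."""

    groups: list
    deviations: np.ndarray
    se: np.ndarray
    reference: object
    variant: str  # "full scalar" | "partial scalar" | "fixed-counterfactual"

    @property
    def ci_lower(self) -> np.ndarray:
        return self.deviations - _Z95 * self.se

    @property
    def ci_upper(self) -> np.ndarray:
        return self.deviations + _Z95 * self.se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "deviation": self.deviations,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "reference": [str(self.reference)] * len(self.groups),
                "variant": [self.variant] * len(self.groups),
            }
        )


class NotComparableError(RuntimeError):
    """Latent means are not comparable below (partial) scalar invariance."""


def _resolve_fit(fit_or_ladder) -> OrdinalFactorResults:
    from .invariance import LadderResult

    if isinstance(fit_or_ladder, LadderResult):
        if not fit_or_ladder.latent_means_comparable:
            raise NotComparableError(
                f"achieved level is {fit_or_ladder.achieved!r}; latent means are "
                "only comparable at (partial) scalar invariance"
            )
        return fit_or_ladder.final
    fit = fit_or_ladder
    if fit.level != "scalar":
        raise NotComparableError(
            f"fit level is {fit.level!r}; latent means require the scalar model"
        )
    return fit


def latent_trend(fit_or_ladder, reference_group=None) -> TrendResult:
    """Standardized latent-mean deviations with delta-method 95% CIs.

    The reference group's deviation is identically 0 with zero-width CI.
    Changing the reference shifts all deviations by a constant (on the
    standardized scale of the new reference).
    """
    fit = _resolve_fit(fit_or_ladder)
    labels = fit.model.group_labels
    if reference_group is None:
        reference_group = labels[0]
    if reference_group not in labels:
        raise ValueError(f"reference group {reference_group!r} not present")
    r = labels.index(reference_group)
    G = len(labels)
    kappas = np.array([float(fit.group_params(g)["kappa"]) for g in range(G)])
    phi_r = float(fit.group_params(r)["phi"])
    dev = (kappas - kappas[r]) / np.sqrt(phi_r)

    se = np.zeros(G)
    if fit.param_cov is not None:
        ik = fit.table.idx["kappa"]
        iph = int(fit.table.idx["phi"][r])
        nfree = fit.params.size
        for g in range(G):
            if g == r:
                continue
            grad = np.zeros(nfree)
            if ik[g] >= 0:
                grad[ik[g]] = 1.0 / np.sqrt(phi_r)
            if ik[r] >= 0:
                grad[ik[r]] = -1.0 / np.sqrt(phi_r)
            if iph >= 0:
                grad[iph] = -(kappas[g] - kappas[r]) / (2.0 * phi_r**1.5)
            se[g] = float(np.sqrt(max(grad @ fit.param_cov @ grad, 0.0)))
    variant = "partial scalar" if fit.free_items.get("intercepts") else "full scalar"
    return TrendResult(
        groups=list(labels), deviations=dev, se=se, reference=reference_group, variant=variant
    )


def freed_vs_fixed(
    model_or_dataset,
    noninvariant_items,
    reference_group=None,
    resid_pairs=None,
) -> dict:
    """Trend comparison: noninvariant intercepts freed vs (wrongly) fixed.

    ``noninvariant_items`` are 0-based item indices whose latent-response
    intercepts are freed in the "accounting" model; the counterfactual keeps
    them constrained.  A freed set exceeding half the items triggers a
    warning (diagnostic mode), not a refusal.
    """
    import warnings

    if isinstance(model_or_dataset, OrdinalFactorModel):
        model = model_or_dataset
    else:
        model = OrdinalFactorModel(model_or_dataset, resid_pairs=resid_pairs)
    items = sorted(set(int(j) for j in noninvariant_items))
    if len(items) > model.K // 2:
        warnings.warn(
            f"freeing {len(items)} of {model.K} items exceeds the partial-invariance budget"
        )
    fixed_fit = model.fit(level="scalar")
    freed_fit = model.fit(level="scalar", free_items={"intercepts": set(items)})
    ref = reference_group if reference_group is not None else model.group_labels[0]
    t_fixed = latent_trend(fixed_fit, ref)
    t_freed = latent_trend(freed_fit, ref)
    t_fixed.variant = "fixed-counterfactual"
    diff = t_freed.deviations - t_fixed.deviations
    return {
        "freed": t_freed,
        "fixed": t_fixed,
        "difference": diff,
        "max_abs_difference": float(np.max(np.abs(diff))),
    }


def icc_oneway(scores, cluster_ids) -> float:
    """One-way random-effects intraclass correlation (ANOVA estimator).

    ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW) with the standard unbalanced
    n0; truncated at 0.  NaN scores are dropped.
    """
    y = np.asarray(scores, dtype=float)
    cl = np.asarray(cluster_ids)
    keep = ~np.isnan(y)
    y, cl = y[keep], cl[keep]
    labels, inv = np.unique(cl, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("ICC needs at least 2 clusters")
    n_i = np.bincount(inv)
    if np.any(n_i < 2):
        raise ValueError("every cluster needs at least 2 observations")
    N = y.size
    sums = np.bincount(inv, weights=y)
    means = sums / n_i
    grand = y.mean()
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(np.sum((y - means[inv]) ** 2))
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - np.sum(n_i**2) / N) / (k - 1)
    if msw == 0.0:
        return 1.0
    icc = (msb - msw) / (msb + (n0 - 1) * msw)
    return float(max(icc, 0.0))


def descriptives(dataset) -> pd.DataFrame:
    """Observed-score descriptives per group: item means, SDs, skewness,
    excess kurtosis, and the 1..C scale mean score."""
    rows = []
    for g in dataset.group_labels():
        X = dataset.group_data(g)
        for j, name in enumerate(dataset.item_names):
            col = X[:, j]
            col = col[~np.isnan(col)]
            rows.append(
                {
                    "group": g,
                    "item": name,
                    "n": col.size,
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=1)),
                    "skewness": float(stats.skew(col)),
                    "excess_kurtosis": float(stats.kurtosis(col)),
                }
            )
        mean_score = np.nanmean(X, axis=1)
        rows.append(
            {
                "group": g,
                "item": "scale_mean",
                "n": int(np.sum(~np.isnan(mean_score))),
                "mean": float(np.nanmean(mean_score)),
                "sd": float(np.nanstd(mean_score, ddof=1)),
                "skewness": float(stats.skew(mean_score, nan_policy="omit")),
                "excess_kurtosis": float(stats.kurtosis(mean_score, nan_policy="omit")),
            }
        )
    return pd.DataFrame(rows)
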