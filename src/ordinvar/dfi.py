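"""Dynamic fit-index cutoffs for ordinal one-factor models.

Fixed universal cutoffs (CFI > 0.95, RMSEA < 0.06) were calibrated on a very
different model class; dynamic fit indices instead simulate from the fitted
model itself to learn what the indices look like for *this* data/model
combination at graded amounts of misspecification:

* Level 0 — data generated from the fitted model exactly (perfect fit);
* Level k (k >= 1) — k omitted residual correlations of magnitude 0.3 are
  added to the generating model while the unmodified model is fitted.

Cutoffs are tail percentiles of the replication distributions: 5th for CFI,
95th for RMSEA and SRMR.  A model whose observed indices are within the
Level-1 cutoffs is judged acceptably close-fitting.

Because the misspecification ladder is nested, the acceptance regions are
made nested too: cutoffs are isotonized across levels (running max for
RMSEA/SRMR, running min for CFI).  This matters when the marginal misfit of
an additional omitted correlation is small — a one-factor model can absorb
part of it by inflating the loadings of the involved items — and raw
percentile cutoffs would otherwise cross by Monte-Carlo noise; the raw
values are kept alongside and a flag records any adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import ConvergenceError, OrdinalFactorModel, OrdinalFactorResults
from .simulate import GroupParams, PopulationSpec, simulate_dataset

__all__ = ["DfiCutoffs", "dfi_cutoffs"]

_MISSPEC_RHO = 0.3


@dataclass
class DfiCutoffs:
    """Simulation-based cutoffs per misspecification level."""

    cutoffs: dict  # level -> {"cfi": x, "rmsea": x, "srmr": x}, nested across levels
    reps: int
    seed: int | None
    misspec: dict  # level -> description
    n_nonconverged: dict
    raw_cutoffs: dict | None = None  # pre-isotonization percentiles
    isotonized: bool = False
    distributions: dict | None = None  # level -> {"cfi": array, ...}

    def acceptable(self, fit: OrdinalFactorResults, level: int = 1) -> bool:
        c = self.cutoffs[level]
        return (
            fit.cfi >= c["cfi"] and fit.rmsea <= c["rmsea"] and fit.srmr <= c["srmr"]
        )

    def to_dict(self) -> dict:
        return {
            "cutoffs": {str(k): v for k, v in self.cutoffs.items()},
            "raw_cutoffs": {str(k): v for k, v in (self.raw_cutoffs or {}).items()},
            "isotonized": self.isotonized,
            "reps": self.reps,
            "seed": self.seed,
            "misspec": {str(k): v for k, v in self.misspec.items()},
            "n_nonconverged": {str(k): v for k, v in self.n_nonconverged.items()},
        }


def _misspec_pairs(K: int, existing: list, k: int) -> list:
    """First k lowest-index item pairs not already modeled."""
    taken = {tuple(sorted(p)) for p in existing}
    out = []
    for pair in itertools.combinations(range(K), 2):
        if pair not in taken:
            out.append(pair)
            if len(out) == k:
                break
    if len(out) < k:
        raise ValueError("not enough unmodeled item pairs for the misspecification level")
    return out


def _dgp_from_fit(fit: OrdinalFactorResults, extra_pairs: list) -> PopulationSpec:
    """Single-group generating spec at the fitted parameter point, with the
    level's omitted residual correlations added."""
    model = fit.model
    pars = fit.group_params(0)
    theta = np.maximum(pars["theta"], 1e-4)
    resid = {tuple(p): float(pars["rc"][q]) for q, p in enumerate(fit.table.resid_pairs)}
    for p in extra_pairs:
        resid[tuple(p)] = _MISSPEC_RHO
    gp = GroupParams(
        kappa=0.0,
        phi=1.0,
        loadings=pars["lam"].copy(),
        intercepts=pars["nu"].copy(),
        thresholds=pars["tau"].copy(),
        theta=theta,
        resid_corr=resid,
    )
    return PopulationSpec(
        n_items=model.K,
        n_categories=model.C,
        groups=["g1"],
        params={"g1": gp},
        n_per_group={"g1": model.moments[0].n},
        missing_rate=0.0,
    )


def dfi_cutoffs(
    fit: OrdinalFactorResults,
    levels=(0, 1, 2),
    reps: int = 200,
    seed: int | None = None,
    keep_distributions: bool = False,
    max_nonconvergence: float = 0.2,
) -> DfiCutoffs:
    """Dynamic fit-index cutoffs for a converged single-group one-factor fit.

    ``reps`` replications per level (>= 50 recommended; smaller values are a
    desk mode with wide Monte-Carlo error).  Raises if more than
    ``max_nonconvergence`` of the replications fail to converge.
    """
    if fit.n_groups != 1:
        raise ValueError("DFI cutoffs are defined for single-group fits")
    if not fit.converged:
        raise ValueError("DFI cutoffs require a converged fit")
    model = fit.model
    rng_root = np.random.default_rng(seed)
    cutoffs, misspec, nonconv, dists = {}, {}, {}, {}
    for lv in levels:
        pairs = _misspec_pairs(model.K, model.resid_pairs, lv) if lv > 0 else []
        spec = _dgp_from_fit(fit, pairs)
        misspec[lv] = (
            "fitted model (no misspecification)"
            if lv == 0
            else f"{lv} omitted residual correlation(s) of {_MISSPEC_RHO} at pairs {pairs}"
        )
        cfis, rmseas, srmrs = [], [], []
        failures = 0
        for rep in range(reps):
            rep_seed = int(rng_root.integers(0, 2**31 - 1))
            ds = simulate_dataset(spec, seed=rep_seed)
            try:
                m = OrdinalFactorModel(ds, resid_pairs=model.resid_pairs)
                r = m.fit(level="configural", compute_se=False)
            except (ConvergenceError, ValueError):
                failures += 1
                continue
            cfis.append(r.cfi)
            rmseas.append(r.rmsea)
            srmrs.append(r.srmr)
        if failures > max_nonconvergence * reps:
            raise RuntimeError(
                f"DFI level {lv}: {failures}/{reps} replications failed to converge"
            )
        nonconv[lv] = failures
        cutoffs[lv] = {
            "cfi": float(np.percentile(cfis, 5)),
            "rmsea": float(np.percentile(rmseas, 95)),
            "srmr": float(np.percentile(srmrs, 95)),
        }
        if keep_distributions:
            dists[lv] = {
                "cfi": np.array(cfis),
                "rmsea": np.array(rmseas),
                "srmr": np.array(srmrs),
            }
    raw = {lv: dict(c) for lv, c in cutoffs.items()}
    ordered = sorted(cutoffs)
    isotonized = False
    for prev, lv in zip(ordered, ordered[1:]):
        for idx, op in (("rmsea", max), ("srmr", max), ("cfi", min)):
            adj = op(cutoffs[lv][idx], cutoffs[prev][idx])
            if adj != cutoffs[lv][idx]:
                isotonized = True
            cutoffs[lv][idx] = adj
    return DfiCutoffs(
        cutoffs=cutoffs,
        reps=reps,
        seed=seed,
        misspec=misspec,
        n_nonconverged=nonconv,
        raw_cutoffs=raw,
        isotonized=isotonized,
        distributions=dists if keep_distributions else None,
    )
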