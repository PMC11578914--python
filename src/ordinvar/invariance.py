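"""Sequential measurement-invariance testing across groups.

The ladder fits the nested sequence configural -> equal thresholds -> equal
loadings -> equal intercepts (scalar) and judges each transition with
delta-fit rules rather than the chi-square difference:

* thresholds and loadings: pass iff ΔRMSEA <= 0.01 and ΔCFI >= -0.004;
* intercepts: pass iff ΔCFI >= -0.002 (the stricter rule, to avoid missing
  consequential noninvariance).

When a step fails, a greedy refit-based search frees the offending item
parameters one item at a time (ties broken by item index) until the rule
passes or more than half the items would need to be freed, in which case the
step is declared noninvariant.  Latent means are only comparable once at
least partial scalar invariance is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import OrdinalFactorModel, OrdinalFactorResults

__all__ = [
    "LadderConfig",
    "StepDecision",
    "LadderResult",
    "InvarianceLadder",
    "run_ladder",
    "compare_models",
    "partial_search",
]

STEPS = ("thresholds", "loadings", "intercepts")
_STEP_LEVEL = {"thresholds": "thresholds", "loadings": "loadings", "intercepts": "scalar"}
_LEVEL_NAME = {
    "configural": "configural",
    "thresholds": "threshold",
    "loadings": "metric",
    "intercepts": "scalar",
}


@dataclass
class LadderConfig:
    """Decision rules and partial-invariance budget for the ladder."""

    steps: tuple = STEPS
    drmsea_max: float = 0.01  # joint rule, thresholds & loadings
    dcfi_min_joint: float = -0.004
    dcfi_min_intercepts: float = -0.002  # strict rule, intercepts
    budget_fraction: float = 0.5  # max fraction of items freed per step

    def __post_init__(self):
        order = [STEPS.index(s) for s in self.steps]
        if order != sorted(order):
            raise ValueError("ladder steps must follow thresholds -> loadings -> intercepts")
        if self.budget_fraction > 0.5:
            raise ValueError("partial-invariance budget cannot exceed half the items")

    def budget(self, K: int) -> int:
        return int(np.floor(self.budget_fraction * K))


@dataclass
class StepDecision:
    step: str
    dcfi: float
    drmsea: float
    passed: bool
    rule: str

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "dcfi": self.dcfi,
            "drmsea": self.drmsea,
            "passed": self.passed,
            "rule": self.rule,
        }


def compare_models(
    restricted: OrdinalFactorResults,
    reference: OrdinalFactorResults,
    step: str,
    config: LadderConfig | None = None,
) -> StepDecision:
    """Delta-fit decision for a nested model transition.

    ΔCFI = CFI_restricted - CFI_reference and ΔRMSEA likewise.  Thresholds
    and loadings pass under the joint ΔRMSEA <= 0.01 and ΔCFI >= -0.004 rule;
    intercepts under ΔCFI >= -0.002.  The chi-square difference is
    deliberately not used.
    """
    config = config or LadderConfig()
    if step not in STEPS:
        raise ValueError(f"unknown step {step!r}")
    if restricted.df <= reference.df:
        raise ValueError(
            "restricted model must have more df than the reference "
            f"({restricted.df} <= {reference.df}); models are not nested"
        )
    dcfi = restricted.cfi - reference.cfi
    drmsea = restricted.rmsea - reference.rmsea
    if step == "intercepts":
        passed = dcfi >= config.dcfi_min_intercepts
        rule = f"dCFI >= {config.dcfi_min_intercepts}"
    else:
        passed = (drmsea <= config.drmsea_max) and (dcfi >= config.dcfi_min_joint)
        rule = f"dRMSEA <= {config.drmsea_max} and dCFI >= {config.dcfi_min_joint}"
    return StepDecision(step=step, dcfi=float(dcfi), drmsea=float(drmsea), passed=bool(passed), rule=rule)


@dataclass
class LadderResult:
    """Per-step fits, decisions, freed parameters and the achieved level."""

    fits: dict  # level tag -> OrdinalFactorResults
    decisions: list  # list of StepDecision in run order
    freed: dict  # step -> ordered list of freed item indices
    achieved: str  # configural / threshold / metric / scalar / partial-*
    final: OrdinalFactorResults
    config: LadderConfig
    partial_failed_step: str | None = None
    audit: list = field(default_factory=list)

    @property
    def latent_means_comparable(self) -> bool:
        return self.achieved in ("scalar", "partial-scalar")

    def summary_table(self) -> pd.DataFrame:
        """MI table in the usual layout: model, chi2, df, CFI, RMSEA(+CI), TLI,
        SRMR, dCFI, dRMSEA, decision."""
        rows = []
        dec_by_level = {}
        for d, tag in zip(self.decisions, list(self.fits)[1:]):
            dec_by_level[tag] = d
        for tag, fit in self.fits.items():
            d = dec_by_level.get(tag)
            lo, hi = fit.indices["rmsea_ci"]
            rows.append(
                {
                    "model": tag,
                    "chi2": fit.chi2,
                    "df": fit.df,
                    "cfi": fit.cfi,
                    "rmsea": fit.rmsea,
                    "rmsea_lo": lo,
                    "rmsea_hi": hi,
                    "tli": fit.tli,
                    "srmr": fit.srmr,
                    "dcfi": np.nan if d is None else d.dcfi,
                    "drmsea": np.nan if d is None else d.drmsea,
                    "decision": "" if d is None else ("pass" if d.passed else "fail"),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "achieved": self.achieved,
            "decisions": [d.to_dict() for d in self.decisions],
            "freed": {k: list(v) for k, v in self.freed.items()},
            "partial_failed_step": self.partial_failed_step,
            "fits": {tag: fit.to_dict() for tag, fit in self.fits.items()},
            "audit": self.audit,
            "config": {
                "drmsea_max": self.config.drmsea_max,
                "dcfi_min_joint": self.config.dcfi_min_joint,
                "dcfi_min_intercepts": self.config.dcfi_min_intercepts,
                "budget_fraction": self.config.budget_fraction,
            },
        }


class InvarianceLadder:
    """Runs the sequential invariance ladder on an :class:`OrdinalFactorModel`."""

    def __init__(self, model: OrdinalFactorModel, config: LadderConfig | None = None):
        if model.n_groups < 2:
            raise ValueError("invariance testing needs at least 2 groups")
        self.model = model
        self.config = config or LadderConfig()

    def run(self) -> LadderResult:
        model, config = self.model, self.config
        free_items: dict = {"thresholds": set(), "loadings": set(), "intercepts": set()}
        fits: dict = {}
        decisions: list = []
        freed: dict = {}
        audit: list = []

        reference = model.fit(level="configural")
        fits["configural"] = reference
        achieved = "configural"
        partial_failed_step = None

        for step in config.steps:
            level = _STEP_LEVEL[step]
            candidate = model.fit(level=level, free_items=free_items)
            decision = compare_models(candidate, reference, step, config)
            audit.append({"step": step, "freed": [], **decision.to_dict()})
            if not decision.passed:
                candidate, decision, freed_items, ok = partial_search(
                    model, reference, step, level, free_items, config, audit
                )
                freed[step] = freed_items
                if not ok:
                    decisions.append(decision)
                    partial_failed_step = step
                    fits[f"{level}_failed"] = candidate
                    break
                free_items = {k: set(v) for k, v in free_items.items()}
                free_items[step] |= set(freed_items)
            else:
                freed[step] = []
            decisions.append(decision)
            fits[level] = candidate
            achieved = _LEVEL_NAME[step]
            if freed[step]:
                achieved = f"partial-{achieved}"
            reference = candidate

        return LadderResult(
            fits=fits,
            decisions=decisions,
            freed=freed,
            achieved=achieved,
            final=reference,
            config=config,
            partial_failed_step=partial_failed_step,
            audit=audit,
        )


def partial_search(
    model: OrdinalFactorModel,
    reference: OrdinalFactorResults,
    step: str,
    level: str,
    free_items: dict,
    config: LadderConfig,
    audit: list | None = None,
):
    """Greedy refit-based search for a passing partial-invariance model.

    One item at a time, frees the item whose release yields the highest CFI
    of the refitted restricted model (ties broken by lower item index), until
    the step's rule passes or the freed count would exceed the budget.

    Returns ``(fit, decision, freed_items, ok)``; ``ok`` is False when the
    budget is exhausted without passing (noninvariance — an explicit status,
    not an exception).
    """
    K = model.K
    budget = config.budget(K)
    freed: list = []
    current = {k: set(v) for k, v in free_items.items()}
    best_fit, best_dec = None, None
    while len(freed) < budget:
        candidates = []
        for j in range(K):
            if j in current[step]:
                continue
            trial = {k: set(v) for k, v in current.items()}
            trial[step].add(j)
            fit = model.fit(level=level, free_items=trial)
            candidates.append((fit.cfi, j, fit, trial))
        if not candidates:
            break
        # highest CFI, ties broken by item index (sort is stable on -cfi, j)
        candidates.sort(key=lambda t: (-t[0], t[1]))
        _, j, fit, trial = candidates[0]
        freed.append(j)
        current = trial
        decision = compare_models(fit, reference, step, config)
        if audit is not None:
            audit.append({"step": step, "freed": list(freed), **decision.to_dict()})
        best_fit, best_dec = fit, decision
        if decision.passed:
            return fit, decision, freed, True
    if best_dec is None:
        # budget zero or nothing to free: re-evaluate the fully restricted model
        fit = model.fit(level=level, free_items=current)
        best_fit = fit
        best_dec = compare_models(fit, reference, step, config)
    return best_fit, best_dec, freed, bool(best_dec.passed)


def run_ladder(
    dataset,
    grouping=None,
    resid_pairs=None,
    config: LadderConfig | None = None,
    model: OrdinalFactorModel | None = None,
) -> LadderResult:
    """Convenience wrapper: build the multigroup model and run the ladder.

    ``dataset`` may be an OrdinalDataset (grouping already attached) or a
    DataFrame with a ``grouping`` column name.
    """
    if model is None:
        if isinstance(dataset, pd.DataFrame):
            model = OrdinalFactorModel.from_dataframe(
                dataset, group_col=grouping or "group", resid_pairs=resid_pairs
            )
        else:
            model = OrdinalFactorModel(dataset, resid_pairs=resid_pairs)
    return InvarianceLadder(model, config).run()
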