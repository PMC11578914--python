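"""Simulation studies validating the pipeline under its design conditions.

Each function runs a self-contained Monte-Carlo experiment — the study
conditions mirror the survey design the package targets (six 4-point items,
loadings 0.65-0.86, groups of ~2000, ~5% missingness) — and returns summary
rates or errors.  They power both the test suite and the reproduction
script; replication counts are arguments so desk-scale runs stay fast.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .effectsize import ItemParams, dmacs
from .invariance import LadderConfig, run_ladder
from .model import ConvergenceError, OrdinalFactorModel
from .polychoric import estimate_polychoric, estimate_thresholds
from .simulate import build_spec, inject_noninvariance, simulate_dataset
from .trends import freed_vs_fixed, latent_trend

RESID_PAIRS = [(2, 3)]


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31 - 1))


# -- polychoric recovery ----------------------------------------------------

def polychoric_bias(seed: int, n: int = 50_000, rhos=(0.2, 0.5, 0.8), reps: int = 10) -> dict:
    """Bias of the polychoric estimator at large n with asymmetric thresholds.

    Bias is the mean estimation error over ``reps`` independent samples of
    size n (a single draw's error is dominated by its own sampling noise,
    ~0.007 SD at this n, not by bias)."""
    t1 = np.array([-0.2, 0.8, 1.5])
    t2 = np.array([-1.0, 0.3, 1.2])
    biases = {}
    for i, rho in enumerate(rhos):
        errs = []
        for r in range(reps):
            rng = np.random.default_rng(_child_seed(seed, 100 * i + r))
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
            y1 = 1 + (z[:, 0][:, None] > t1).sum(axis=1)
            y2 = 1 + (z[:, 1][:, None] > t2).sum(axis=1)
            tab = np.zeros((4, 4))
            np.add.at(tab, (y1 - 1, y2 - 1), 1)
            e1 = estimate_thresholds(np.bincount(y1, minlength=5)[1:])
            e2 = estimate_thresholds(np.bincount(y2, minlength=5)[1:])
            errs.append(estimate_polychoric(tab, e1, e2, return_var=False) - rho)
        biases[rho] = float(np.mean(errs))
    return {"bias": biases, "max_abs_bias": float(max(abs(b) for b in biases.values()))}


# -- CFA self-consistency ---------------------------------------------------

def cfa_self_consistency(seed: int = 0) -> dict:
    """Fit exact model-implied moments: F at the optimum and parameter error."""
    from .model import build_parameter_table, implied_moments
    from .polychoric import PolychoricMoments

    K, C = 6, 4
    spec = build_spec(n_groups=1)
    gp = spec.params["g1"]
    pars = {
        "tau": gp.thresholds,
        "lam": gp.loadings,
        "sd": np.ones(K),
        "nu": np.zeros(K),
        "kappa": 0.0,
        "phi": 1.0,
        "rc": np.array([0.25]),
    }
    sigma, ex = implied_moments(pars, K, C, RESID_PAIRS)
    tau = sigma[: K * (C - 1)].reshape(K, C - 1)
    P = np.eye(K)
    iu = np.triu_indices(K, 1)
    P[iu] = sigma[K * (C - 1):]
    P.T[iu] = P[iu]
    mom = PolychoricMoments(
        thresholds=tau, corr=P, gamma=None, n=10_000,
        pairwise_n=np.full((K, K), 10_000), group="g1",
    )
    model = OrdinalFactorModel.from_moments([mom], resid_pairs=RESID_PAIRS)
    fit = model.fit(level="configural", compute_se=False)
    est = fit.group_params(0)
    err = max(
        float(np.max(np.abs(est["tau"] - pars["tau"]))),
        float(np.max(np.abs(est["lam"] - pars["lam"]))),
        float(abs(est["rc"][0] - 0.25)),
    )
    return {"fmin": fit.fmin, "max_param_error": err}


def cfa_bruteforce_agreement(seed: int = 0, n: int = 4000) -> dict:
    """3-item single-group model: DWLS solution vs Nelder-Mead brute force."""
    from scipy.optimize import minimize

    spec = build_spec(
        n_groups=1, n_items=3, loadings=[0.8, 0.7, 0.6],
        thresholds=np.array([[-0.6, 0.2, 1.0], [-0.3, 0.5, 1.3], [0.0, 0.7, 1.5]]),
        resid_corr={}, n_per_group=n,
    )
    ds = simulate_dataset(spec, seed=seed)
    model = OrdinalFactorModel(ds)
    fit = model.fit(level="configural", compute_se=False)
    mom = model.moments[0]
    s, w = mom.stats, mom.weights

    def F(p):
        tau = p[:9].reshape(3, 3)
        lam = p[9:12]
        P = np.outer(lam, lam)
        sigma = np.concatenate([tau.ravel(), P[np.triu_indices(3, 1)]])
        r = s - sigma
        return float(r @ (r / w))

    p0 = np.concatenate([mom.thresholds.ravel(), [0.5, 0.5, 0.5]])
    res = minimize(F, p0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000})
    est = fit.group_params(0)
    mine = np.concatenate([est["tau"].ravel(), est["lam"]])
    return {
        "max_abs_diff": float(np.max(np.abs(mine - res.x))),
        "fmin_dwls": fit.fmin,
        "fmin_bruteforce": float(res.fun),
    }


# -- ladder operating characteristics --------------------------------------

def ladder_false_alarm(seed: int, reps: int = 200, n_groups: int = 4, n: int = 2000) -> dict:
    """Share of fully invariant replications in which every step passes."""
    spec = build_spec(n_groups=n_groups, n_per_group=n, missing_rate=0.055)
    passes = 0
    for r in range(reps):
        ds = simulate_dataset(spec, seed=_child_seed(seed, r))
        try:
            lr = run_ladder(ds, resid_pairs=RESID_PAIRS)
        except ConvergenceError:
            continue
        if lr.achieved == "scalar" and not any(lr.freed.values()):
            passes += 1
    return {"pass_rate": passes / reps, "reps": reps}


def dif_detection(seed: int, reps: int = 200, n_groups: int = 4, n: int = 2000,
                  item: int = 5, shift: float = 0.5) -> dict:
    """Intercept DIF on one item in half the groups: step failure and
    correct first-freed-item rates."""
    spec = build_spec(n_groups=n_groups, n_per_group=n, missing_rate=0.055)
    targets = [f"g{i + 1}" for i in range(n_groups // 2, n_groups)]
    spec = inject_noninvariance(spec, item=item, parameter="intercept",
                                shift=shift, target_groups=targets)
    fail_step, correct_first = 0, 0
    for r in range(reps):
        ds = simulate_dataset(spec, seed=_child_seed(seed, r))
        try:
            lr = run_ladder(ds, resid_pairs=RESID_PAIRS)
        except ConvergenceError:
            continue
        freed = lr.freed.get("intercepts", [])
        if freed or lr.partial_failed_step == "intercepts":
            fail_step += 1
        if freed and freed[0] == item:
            correct_first += 1
    return {
        "intercept_step_fail_rate": fail_step / reps,
        "correct_item_first_rate": correct_first / reps,
        "reps": reps,
    }


# -- d_MACS oracle ----------------------------------------------------------

def dmacs_mc_agreement(seed: int, n_mc: int = 1_000_000,
                       lams=(0.65, 0.75, 0.86), shifts=(0.1, 0.3, 0.5)) -> dict:
    """Quadrature d_MACS vs Monte-Carlo integration over a (lambda, shift) grid."""
    tau = np.array([-0.674, 0.0, 0.674])
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal(n_mc)
    diffs = []
    for lam in lams:
        theta = 1 - lam**2
        ref = ItemParams(thresholds=tau, loading=lam, theta=theta)
        for sh in shifts:
            foc = ItemParams(thresholds=tau, loading=lam, intercept=sh, theta=theta)
            res = dmacs(ref, foc)
            z_r = (tau[:, None] - lam * eta[None, :]) / np.sqrt(theta)
            z_f = (tau[:, None] - sh - lam * eta[None, :]) / np.sqrt(theta)
            gap = (4 - ndtr(z_f).sum(axis=0)) - (4 - ndtr(z_r).sum(axis=0))
            d_mc = float(np.sqrt(np.mean(gap**2)) / res.pooled_sd)
            diffs.append(abs(res.d - d_mc))
    return {"max_abs_diff": float(max(diffs))}


# -- trend recovery ---------------------------------------------------------

def trend_coverage(seed: int, reps: int = 200, n: int = 2000) -> dict:
    """95% CI coverage of standardized latent-mean deviations."""
    truth = np.array([0.0, 0.0, 0.2, 0.3])
    spec = build_spec(n_groups=4, n_per_group=n, kappa=truth, missing_rate=0.055)
    hits, total = 0, 0
    for r in range(reps):
        ds = simulate_dataset(spec, seed=_child_seed(seed, r))
        try:
            model = OrdinalFactorModel(ds, resid_pairs=RESID_PAIRS)
            fit = model.fit(level="scalar")
        except ConvergenceError:
            continue
        tr = latent_trend(fit, "g1")
        for g in range(1, 4):
            total += 1
            if tr.ci_lower[g] <= truth[g] <= tr.ci_upper[g]:
                hits += 1
    return {"coverage": hits / total if total else np.nan, "n_intervals": total}


def freed_vs_fixed_drift(seed: int, reps: int = 100, n_groups: int = 10,
                         n: int = 2000, endpoint_shift: float = 0.10) -> dict:
    """Small monotone intercept drift on one item across cohorts: how much do
    freed and fixed trends differ?"""
    base = build_spec(n_groups=n_groups, n_per_group=n, missing_rate=0.055)
    spec = base
    for gi in range(1, n_groups):
        spec = inject_noninvariance(
            spec, item=5, parameter="intercept",
            shift=endpoint_shift * gi / (n_groups - 1), target_groups=[f"g{gi + 1}"],
        )
    below = 0
    maxima = []
    for r in range(reps):
        ds = simulate_dataset(spec, seed=_child_seed(seed, r))
        try:
            cmp = freed_vs_fixed(ds, [5], resid_pairs=RESID_PAIRS)
        except ConvergenceError:
            continue
        maxima.append(cmp["max_abs_difference"])
        if cmp["max_abs_difference"] < 0.05:
            below += 1
    return {
        "rate_below_0.05": below / reps,
        "median_max_distortion": float(np.median(maxima)),
        "reps": reps,
    }


def freed_vs_fixed_age_bias(seed: int, reps: int = 50, n_groups: int = 5,
                            n: int = 2000, shift: float = -0.5) -> dict:
    """Two same-direction intercept shifts in the oldest groups: size and sign
    of the fixed model's trend bias relative to the freed model."""
    spec = build_spec(n_groups=n_groups, n_per_group=n, missing_rate=0.055)
    old = [f"g{n_groups - 1}", f"g{n_groups}"]
    for item in (1, 2):
        spec = inject_noninvariance(spec, item=item, parameter="intercept",
                                    shift=shift, target_groups=old)
    biases = []
    for r in range(reps):
        ds = simulate_dataset(spec, seed=_child_seed(seed, r))
        try:
            cmp = freed_vs_fixed(ds, [1, 2], resid_pairs=RESID_PAIRS)
        except ConvergenceError:
            continue
        # bias of the fixed model in the shifted groups (freed model = truth-consistent)
        d = cmp["fixed"].deviations - cmp["freed"].deviations
        biases.append(d[-2:].mean())
    biases = np.array(biases)
    sign = np.sign(shift)
    return {
        "mean_bias": float(biases.mean()),
        "share_exceeding_0.1_with_sign": float(np.mean(sign * biases > 0.1)),
        "reps": reps,
    }


# -- parallel analysis ------------------------------------------------------

def parallel_retention(seed: int, n_seeds: int = 20, n: int = 2000,
                       n_sets: int = 200) -> dict:
    """Retention rates: one-factor DGP (expect 1) and a two-orthogonal-factor
    DGP built from stacked 3-item blocks (expect 2)."""
    from .dimensionality import parallel_analysis
    from .simulate import OrdinalDataset

    one_ok, ratio_ok, two_ok = 0, 0, 0
    spec1 = build_spec(n_groups=1, n_per_group=n, missing_rate=0.0)
    spec3 = build_spec(n_groups=1, n_items=3, loadings=[0.8, 0.8, 0.8],
                       thresholds=np.array([[-0.6, 0.2, 1.0]] * 3),
                       resid_corr={}, n_per_group=n)
    for s in range(n_seeds):
        ds = simulate_dataset(spec1, seed=_child_seed(seed, s))
        rep = parallel_analysis(ds, n_sets=n_sets, seed=_child_seed(seed, 1000 + s))
        if rep.n_retained == 1:
            one_ok += 1
        if rep.ratio_first_second > 4:
            ratio_ok += 1
        da = simulate_dataset(spec3, seed=_child_seed(seed, 2000 + s))
        db = simulate_dataset(spec3, seed=_child_seed(seed, 3000 + s))
        stacked = OrdinalDataset(
            data=np.hstack([da.data, db.data]),
            groups=da.groups, n_categories=4,
            item_names=[f"item_{j + 1}" for j in range(6)],
        )
        rep2 = parallel_analysis(stacked, n_sets=n_sets, seed=_child_seed(seed, 4000 + s))
        if rep2.n_retained == 2:
            two_ok += 1
    return {
        "one_factor_rate": one_ok / n_seeds,
        "ratio_gt4_rate": ratio_ok / n_seeds,
        "two_factor_rate": two_ok / n_seeds,
        "n_seeds": n_seeds,
    }


# -- dynamic fit indices ----------------------------------------------------

def dfi_check(seed: int, reps: int = 100, n: int = 2000) -> dict:
    """Cutoff monotonicity across levels and Level-0 self-acceptance."""
    from .dfi import dfi_cutoffs

    spec = build_spec(n_groups=1, n_per_group=n, missing_rate=0.0)
    ds = simulate_dataset(spec, seed=seed)
    model = OrdinalFactorModel(ds, resid_pairs=RESID_PAIRS)
    fit = model.fit(level="configural")
    cuts = dfi_cutoffs(fit, reps=reps, seed=seed, keep_distributions=True)
    c = cuts.cutoffs
    rmsea_mono = c[0]["rmsea"] <= c[1]["rmsea"] <= c[2]["rmsea"]
    cfi_mono = c[0]["cfi"] >= c[1]["cfi"] >= c[2]["cfi"]
    d0 = cuts.distributions[0]
    self_acc = float(
        np.mean(
            (d0["cfi"] >= c[0]["cfi"])
            & (d0["rmsea"] <= c[0]["rmsea"])
            & (d0["srmr"] <= c[0]["srmr"])
        )
    )
    return {
        "rmsea_monotone": bool(rmsea_mono),
        "cfi_monotone": bool(cfi_mono),
        "level0_self_acceptance": self_acc,
        "cutoffs": {str(k): v for k, v in c.items()},
        "reps": reps,
    }
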