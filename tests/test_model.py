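"""Ordinal CFA: implied moments, DWLS fit, robust statistic, indices, omega."""

import numpy as np
import pytest
from scipy.special import ndtr

from ordinvar.model import (
    OrdinalFactorModel,
    build_parameter_table,
    fit_indices,
    implied_moments,
    omega_reliability,
)
from ordinvar.polychoric import PolychoricMoments
from ordinvar.simulate import DEFAULT_LOADINGS, build_spec, simulate_dataset


def _pars(K=2, lam=0.8, tau=(-0.674, 0.0, 0.674), rc=()):
    return {
        "tau": np.tile(np.asarray(tau, float), (K, 1)),
        "lam": np.full(K, lam),
        "sd": np.ones(K),
        "nu": np.zeros(K),
        "kappa": 0.0,
        "phi": 1.0,
        "rc": np.asarray(rc, float),
    }


class TestImpliedMoments:
    def test_product_rule(self):
        sigma, ex = implied_moments(_pars(K=2, lam=0.8), 2, 4, [])
        assert ex["P"][0, 1] == pytest.approx(0.64)

    def test_zero_loadings_identity_plus_residual_pairs(self):
        pars = _pars(K=3, lam=0.0, rc=[0.3])
        sigma, ex = implied_moments(pars, 3, 4, [(0, 1)])
        P = ex["P"]
        assert P[0, 1] == pytest.approx(0.3)
        assert P[0, 2] == pytest.approx(0.0)
        assert P[1, 2] == pytest.approx(0.0)

    def test_category_probabilities_sum_to_one(self):
        pars = _pars(K=4, lam=0.7)
        pars["nu"][:] = 0.2
        pars["kappa"], pars["phi"] = 0.4, 1.3
        pars["sd"][:] = 1.1
        sigma, _ = implied_moments(pars, 4, 4, [])
        t = sigma[: 4 * 3].reshape(4, 3)
        for j in range(4):
            probs = np.diff(np.concatenate([[0.0], ndtr(t[j]), [1.0]]))
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(probs > 0)


class TestFit:
    def test_self_consistency_on_exact_moments(self):
        from ordinvar.validation import cfa_self_consistency

        out = cfa_self_consistency()
        assert out["fmin"] < 1e-8
        assert out["max_param_error"] < 1e-4  # 4-decimal recovery

    def test_loading_recovery_single_group(self, single_group_fit):
        est = single_group_fit.loadings.to_numpy().ravel()
        assert np.max(np.abs(est - DEFAULT_LOADINGS)) < 0.03

    def test_group_order_permutation_symmetry(self, invariant_dataset, multigroup_model):
        base = multigroup_model.fit(level="configural", compute_se=False)
        perm = OrdinalFactorModel.from_moments(
            multigroup_model.moments[::-1],
            group_labels=multigroup_model.group_labels[::-1],
            resid_pairs=[(2, 3)],
        )
        alt = perm.fit(level="configural", compute_se=False)
        assert alt.fmin == pytest.approx(base.fmin, rel=1e-6, abs=1e-12)
        assert alt.cfi == pytest.approx(base.cfi, abs=1e-6)
        assert alt.rmsea == pytest.approx(base.rmsea, abs=1e-6)

    def test_item_relabeling_permutes_estimates(self, single_group_dataset):
        from ordinvar.simulate import OrdinalDataset

        perm = [3, 0, 5, 1, 4, 2]
        ds = single_group_dataset
        ds2 = OrdinalDataset(
            data=ds.data[:, perm],
            groups=ds.groups,
            n_categories=4,
            item_names=[ds.item_names[j] for j in perm],
        )
        f1 = OrdinalFactorModel(ds).fit(compute_se=False)
        f2 = OrdinalFactorModel(ds2).fit(compute_se=False)
        lam1 = f1.group_params(0)["lam"]
        lam2 = f2.group_params(0)["lam"]
        assert np.allclose(lam2, lam1[perm], atol=1e-6)
        assert f2.fmin == pytest.approx(f1.fmin, rel=1e-6, abs=1e-12)

    def test_constraint_bookkeeping_df_steps(self, multigroup_model):
        """df grows by exactly the number of independent equality constraints:
        6(G-1) at the threshold step, 5(G-1) at loadings and intercepts."""
        G = multigroup_model.n_groups
        dfs = {}
        for lev in ("configural", "thresholds", "loadings", "scalar"):
            dfs[lev] = multigroup_model.fit(level=lev, compute_se=False).df
        assert dfs["thresholds"] - dfs["configural"] == 6 * (G - 1)
        assert dfs["loadings"] - dfs["thresholds"] == 5 * (G - 1)
        assert dfs["scalar"] - dfs["loadings"] == 5 * (G - 1)

    def test_unidentified_model_rejected(self):
        # 2 items, 2 categories: 3 moments per group but 4 free parameters
        spec = build_spec(n_groups=1, n_items=2, n_categories=2,
                          loadings=[0.8, 0.7], thresholds=np.array([[0.0], [0.3]]),
                          resid_corr={}, n_per_group=500)
        ds = simulate_dataset(spec, seed=5)
        model = OrdinalFactorModel(ds)
        with pytest.raises(ValueError, match="not identified"):
            model.fit(check_identification=True)

    def test_bruteforce_agreement_three_items(self):
        from ordinvar.validation import cfa_bruteforce_agreement

        out = cfa_bruteforce_agreement(seed=3)
        assert out["max_abs_diff"] < 1e-3

    def test_bruteforce_agreement_four_items_overidentified(self):
        """4-item model (df = 2): the DWLS optimizer's solution matches a
        derivative-free Nelder-Mead minimization of the same fit function."""
        from scipy.optimize import minimize

        spec = build_spec(n_groups=1, n_items=4, loadings=[0.8, 0.7, 0.6, 0.75],
                          thresholds=np.array([[-0.6, 0.2, 1.0]] * 4),
                          resid_corr={}, n_per_group=3000)
        ds = simulate_dataset(spec, seed=9)
        model = OrdinalFactorModel(ds)
        fit = model.fit(compute_se=False)
        mom = model.moments[0]
        s, w = mom.stats, mom.weights

        def F(p):
            tau = p[:12].reshape(4, 3)
            lam = p[12:]
            P = np.outer(lam, lam)
            sigma = np.concatenate([tau.ravel(), P[np.triu_indices(4, 1)]])
            r = s - sigma
            return float(r @ (r / w))

        p0 = np.concatenate([mom.thresholds.ravel(), np.full(4, 0.6)])
        res = minimize(F, p0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-13,
                                "maxiter": 40000, "maxfev": 40000})
        est = np.concatenate([fit.group_params(0)["tau"].ravel(),
                              fit.group_params(0)["lam"]])
        assert np.max(np.abs(est - res.x)) < 1e-3

    def test_serialization_roundtrip(self, single_group_fit):
        d = single_group_fit.to_dict()
        assert d["df"] == single_group_fit.df
        assert len(d["params"]) == len(d["param_names"])
        assert "cfi" in d and "bse" in d


class TestFitIndices:
    class _Stub:
        def __init__(self, chi2, df, K=6, resid=None):
            self.chi2, self.df = chi2, df
            self.model = type("M", (), {"K": K})()
            self._resid = resid if resid is not None else [np.zeros(K * 3 + 15)]

        def residuals(self):
            return self._resid

    def test_rmsea_formula(self):
        out = fit_indices(self._Stub(200.0, 50), self._Stub(5000.0, 15), 1000, 1)
        assert out["rmsea"] == pytest.approx(np.sqrt(150 / (50 * 999)), abs=1e-6)
        assert out["rmsea"] == pytest.approx(0.0548, abs=5e-4)

    def test_cfi_formula(self):
        out = fit_indices(self._Stub(200.0, 50), self._Stub(5000.0, 15), 1000, 1)
        assert out["cfi"] == pytest.approx(1 - 150 / 4985, abs=1e-9)
        assert out["cfi"] == pytest.approx(0.9699, abs=5e-4)

    def test_perfect_fit_guards(self):
        out = fit_indices(self._Stub(40.0, 50), self._Stub(5000.0, 15), 1000, 1)
        assert out["rmsea"] == 0.0
        assert out["cfi"] == 1.0

    def test_degenerate_baseline_still_defined(self):
        out = fit_indices(self._Stub(200.0, 50), self._Stub(60.0, 15), 1000, 1)
        assert 0.0 <= out["cfi"] <= 1.0

    def test_multigroup_rmsea_sqrt_g_convention(self):
        one = fit_indices(self._Stub(200.0, 50), self._Stub(5000.0, 15), 1000, 1)
        two = fit_indices(self._Stub(200.0, 50), self._Stub(5000.0, 15), 1002, 2)
        ratio = two["rmsea"] / np.sqrt(200 - 50) * np.sqrt(50 * (1002 - 2))
        assert ratio == pytest.approx(np.sqrt(2), rel=1e-9)
        assert two["rmsea"] > one["rmsea"]


class TestOmega:
    def _fit_from_point(self, lam, theta, rc=None):
        K, C = 6, 4
        pairs = [(2, 3)] if rc is not None else []
        pars = {
            "tau": np.tile([-0.674, 0.0, 0.674], (K, 1)),
            "lam": np.full(K, lam),
            "sd": np.sqrt(np.full(K, lam) ** 2 + theta),
            "nu": np.zeros(K),
            "kappa": 0.0,
            "phi": 1.0,
            "rc": np.array([rc] if rc is not None else []),
        }
        sigma, ex = implied_moments(pars, K, C, pairs)
        tau = sigma[: K * 3].reshape(K, 3)
        P = np.eye(K)
        iu = np.triu_indices(K, 1)
        P[iu] = sigma[K * 3:]
        P.T[iu] = P[iu]
        mom = PolychoricMoments(thresholds=tau, corr=P, gamma=None, n=1000,
                                pairwise_n=np.full((K, K), 1000))
        model = OrdinalFactorModel.from_moments([mom], resid_pairs=pairs)
        return model.fit(compute_se=False)

    def test_formula_case(self):
        # K=6, lam=0.8, phi=1, theta=0.36: omega = 23.04 / 25.20
        fit = self._fit_from_point(lam=0.8, theta=0.36)
        assert omega_reliability(fit) == pytest.approx(23.04 / 25.20, abs=1e-4)

    def test_zero_loadings_zero_omega(self):
        fit = self._fit_from_point(lam=1e-8, theta=1.0)
        assert omega_reliability(fit) == pytest.approx(0.0, abs=1e-6)

    def test_residual_covariance_lowers_omega(self):
        plain = omega_reliability(self._fit_from_point(0.8, 0.36))
        with_rc = omega_reliability(self._fit_from_point(0.8, 0.36, rc=0.3))
        assert with_rc < plain
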