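"""Polychoric moments: thresholds, correlations, asymptotic covariance."""

import warnings

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from ordinvar._bvn import bvn_cdf
from ordinvar.polychoric import (
    DegenerateItemError,
    _cell_probs,
    estimate_polychoric,
    estimate_thresholds,
    moments_and_weights,
)
from ordinvar.simulate import build_spec, simulate_dataset


def test_bvn_cdf_matches_scipy():
    rng = np.random.default_rng(0)
    x, y = rng.uniform(-3, 3, 50), rng.uniform(-3, 3, 50)
    for rho in (-0.95, -0.5, 0.0, 0.6, 0.93, 0.999):
        ref = [
            multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf([a, b])
            for a, b in zip(x, y)
        ]
        assert np.allclose(bvn_cdf(x, y, rho), ref, atol=1e-12)


class TestThresholds:
    def test_quartile_proportions(self):
        tau = estimate_thresholds([250, 250, 250, 250])
        assert np.allclose(tau, [-0.67448975, 0.0, 0.67448975], atol=1e-8)

    def test_two_category_median(self):
        assert np.allclose(estimate_thresholds([500, 500]), [0.0])

    def test_recovery_at_large_n(self):
        truth = np.array([-1.0, 0.0, 1.0])
        spec = build_spec(
            n_groups=1, n_per_group=100_000, thresholds=np.tile(truth, (6, 1)),
            missing_rate=0.0,
        )
        ds = simulate_dataset(spec, seed=2)
        counts = np.bincount(ds.data[:, 0].astype(int), minlength=5)[1:]
        est = estimate_thresholds(counts)
        assert np.max(np.abs(est - truth)) < 0.02

    def test_degenerate_item_rejected(self):
        with pytest.raises(DegenerateItemError):
            estimate_thresholds([0, 1000, 0, 0])

    def test_interior_empty_category_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="collapsed"):
            tau = estimate_thresholds([400, 0, 300, 300])
        assert tau.size == 2  # one threshold lost to the collapse

    def test_interior_empty_strict_mode_errors(self):
        with pytest.raises(DegenerateItemError, match="strict"):
            estimate_thresholds([400, 0, 300, 300], strict=True)


class TestPolychoric:
    TAU = np.array([-0.674, 0.0, 0.674])

    def test_independence_table_gives_zero(self):
        m1 = np.array([0.25, 0.35, 0.25, 0.15])
        m2 = np.array([0.4, 0.3, 0.2, 0.1])
        table = np.outer(m1, m2) * 1e6
        t1 = estimate_thresholds(m1 * 1e6)
        t2 = estimate_thresholds(m2 * 1e6)
        rho = estimate_polychoric(table, t1, t2, return_var=False)
        assert abs(rho) < 1e-3

    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8, -0.6])
    def test_exact_expected_table_inversion(self, rho):
        """The estimator inverts a table of exact bivariate-normal rectangle
        probabilities to the generating correlation."""
        table = _cell_probs(rho, self.TAU, self.TAU) * 1e6
        est = estimate_polychoric(table, self.TAU, self.TAU, return_var=False)
        assert abs(est - rho) < 1e-3

    def test_perfect_association_clips_with_warning(self):
        table = np.diag([250.0, 250.0, 250.0, 250.0])
        with pytest.warns(UserWarning, match="boundary"):
            rho = estimate_polychoric(table, self.TAU, self.TAU, return_var=False)
        assert rho == pytest.approx(0.999)

    def test_zero_margin_rejected(self):
        table = np.zeros((4, 4))
        table[0, 0] = 100
        table[1, 1] = 100
        with pytest.raises(ValueError, match="margin"):
            # margin zero in rows/cols 3-4
            estimate_polychoric(table, self.TAU, self.TAU)

    def test_category_reversal_symmetry(self):
        """Reversing both items leaves rho unchanged; reversing one flips sign."""
        rng = np.random.default_rng(4)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=20_000)
        y1 = 1 + (z[:, 0][:, None] > self.TAU).sum(axis=1)
        y2 = 1 + (z[:, 1][:, None] > self.TAU).sum(axis=1)

        def rho_of(a, b):
            tab = np.zeros((4, 4))
            np.add.at(tab, (a - 1, b - 1), 1)
            ta = estimate_thresholds(np.bincount(a, minlength=5)[1:])
            tb = estimate_thresholds(np.bincount(b, minlength=5)[1:])
            return estimate_polychoric(tab, ta, tb, return_var=False)

        base = rho_of(y1, y2)
        both = rho_of(5 - y1, 5 - y2)
        one = rho_of(5 - y1, y2)
        assert both == pytest.approx(base, abs=1e-9)
        assert one == pytest.approx(-base, abs=1e-9)

    def test_consistency_small_bias_at_large_n(self):
        from ordinvar.validation import polychoric_bias

        out = polychoric_bias(seed=11, n=50_000)
        assert out["max_abs_bias"] < 0.01


class TestMomentsAndWeights:
    def test_complete_data_pairwise_n_equals_group_n(self):
        spec = build_spec(n_groups=1, n_per_group=1500, missing_rate=0.0)
        ds = simulate_dataset(spec, seed=6)
        mom = moments_and_weights(ds, "g1")
        assert np.all(mom.pairwise_n == 1500)

    def test_mcar_pairwise_n_within_binomial_bounds(self):
        from scipy.stats import binom

        n, m = 4000, 0.05
        spec = build_spec(n_groups=1, n_per_group=n, missing_rate=m)
        ds = simulate_dataset(spec, seed=8)
        mom = moments_and_weights(ds, "g1")
        lo, hi = binom.ppf([0.005, 0.995], n, (1 - m) ** 2)
        off = mom.pairwise_n[np.triu_indices(6, 1)]
        assert np.all((off >= lo) & (off <= hi))

    def test_moment_vector_invariants(self, multigroup_model):
        for mom in multigroup_model.moments:
            P = mom.corr
            assert np.allclose(P, P.T)
            assert np.allclose(np.diag(P), 1.0)
            assert np.all(np.abs(P[np.triu_indices(6, 1)]) < 1)
            assert np.all(np.diff(mom.thresholds, axis=1) > 0)
            assert np.all(np.diag(mom.gamma) > 0)

    def test_asymptotic_variance_matches_jackknife(self):
        """Delete-a-block jackknife (200 blocks) reproduces the influence-based
        variance of a polychoric correlation within 20% relative error."""
        spec = build_spec(n_groups=1, n_per_group=5000, missing_rate=0.0)
        ds = simulate_dataset(spec, seed=12)
        mom = moments_and_weights(ds, "g1")
        n = mom.n
        var_infl = mom.gamma[18, 18] / n  # first correlation (items 1,2)

        X = ds.data
        n_blocks = 200
        idx = np.arange(n)
        est = []
        for b in range(n_blocks):
            keep = idx[idx % n_blocks != b]
            y1 = X[keep, 0].astype(int)
            y2 = X[keep, 1].astype(int)
            tab = np.zeros((4, 4))
            np.add.at(tab, (y1 - 1, y2 - 1), 1)
            t1 = estimate_thresholds(np.bincount(y1, minlength=5)[1:])
            t2 = estimate_thresholds(np.bincount(y2, minlength=5)[1:])
            est.append(estimate_polychoric(tab, t1, t2, return_var=False))
        est = np.array(est)
        var_jack = (n_blocks - 1) / n_blocks * np.sum((est - est.mean()) ** 2)
        assert abs(var_jack - var_infl) / var_infl < 0.20

    def test_asymptotic_variances_scale_inversely_with_n(self):
        """Variance of each statistic ~ 1/n over a 4-point n grid (15% rel)."""
        ns = [1000, 2000, 4000, 8000]
        diags = []
        for n in ns:
            spec = build_spec(n_groups=1, n_per_group=n, missing_rate=0.0)
            ds = simulate_dataset(spec, seed=14)
            mom = moments_and_weights(ds, "g1")
            # the reported variance of s is gamma/n, so diag(gamma) should be
            # ~constant in n (its own estimation noise averaged over the vector)
            diags.append(np.diag(mom.gamma))
        base = np.mean(diags[-1])
        for d in diags[:-1]:
            assert abs(np.mean(d) / base - 1.0) < 0.15

    def test_degenerate_item_propagates_identity(self):
        spec = build_spec(n_groups=1, n_per_group=200)
        ds = simulate_dataset(spec, seed=1)
        ds.data[:, 2] = 1.0  # item 3 constant
        with pytest.raises(DegenerateItemError, match="item 3"):
            moments_and_weights(ds, "g1")

    def test_export_report(self, multigroup_model):
        rep = multigroup_model.moments[0].to_dict()
        assert set(rep) >= {"thresholds", "polychoric_corr", "pairwise_n", "n"}
        assert len(rep["polychoric_corr"]) == 6
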