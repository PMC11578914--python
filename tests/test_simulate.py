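"""Generator: defaults, validation, determinism and distributional correctness."""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import pearsonr

from ordinvar.simulate import (
    DEFAULT_LOADINGS,
    OrdinalDataset,
    build_spec,
    inject_noninvariance,
    simulate_dataset,
)


class TestBuildSpec:
    def test_default_spec_is_fully_invariant(self):
        spec = build_spec(n_groups=3)
        ref = spec.params[spec.groups[0]]
        for g in spec.groups[1:]:
            p = spec.params[g]
            assert np.array_equal(p.loadings, ref.loadings)
            assert np.array_equal(p.thresholds, ref.thresholds)
            assert p.kappa == 0.0 and p.phi == 1.0
        # delta scaling in the reference group: Var(y*) = 1
        assert np.allclose(ref.loadings**2 + ref.theta, 1.0)

    def test_year_gender_age_grid(self):
        spec = build_spec(year_gender_age=(10, 2, 5), n_per_group=1000)
        assert len(spec.groups) == 100
        assert spec.total_n() == 100_000

    def test_nonmonotone_thresholds_rejected(self):
        with pytest.raises(ValueError, match="item 2"):
            build_spec(
                n_groups=1,
                thresholds=np.array(
                    [[-0.3, 0.5, 1.4], [0.9, 0.7, 1.5], [-0.2, 0.6, 1.4],
                     [0.0, 0.8, 1.6], [0.1, 0.9, 1.7], [-0.4, 0.5, 1.3]]
                ),
            )

    def test_invalid_residual_correlation_rejected(self):
        with pytest.raises(ValueError, match="residual correlation"):
            build_spec(n_groups=1, resid_corr={(0, 1): 1.2})


class TestSimulate:
    def test_seed_determinism(self, invariant_spec):
        a = simulate_dataset(invariant_spec, seed=5)
        b = simulate_dataset(invariant_spec, seed=5)
        assert np.array_equal(a.data, b.data, equal_nan=True)
        assert np.array_equal(a.groups, b.groups)

    def test_adding_a_group_does_not_perturb_existing_streams(self):
        s3 = build_spec(n_groups=3, n_per_group=500)
        s4 = build_spec(n_groups=4, n_per_group=500)
        d3 = simulate_dataset(s3, seed=9)
        d4 = simulate_dataset(s4, seed=9)
        assert np.array_equal(d3.data, d4.data[: len(d3.data)], equal_nan=True)

    def test_category_frequencies_match_normal_ogive(self):
        """Large-n category proportions within 3 MC SEs of the analytic
        probabilities Phi((tau_c - nu)/sd) differences."""
        n = 100_000
        tau = np.array([-0.674, 0.0, 0.674])
        spec = build_spec(
            n_groups=1, n_per_group=n, loadings=np.full(6, 0.8),
            thresholds=np.tile(tau, (6, 1)), resid_corr={}, missing_rate=0.0,
        )
        ds = simulate_dataset(spec, seed=13)
        edges = np.concatenate([[-np.inf], tau, [np.inf]])
        probs = np.diff(ndtr(edges))  # y* ~ N(0, 1) under delta scaling
        for j in range(6):
            counts = np.bincount(ds.data[:, j].astype(int), minlength=5)[1:]
            for c in range(4):
                se = np.sqrt(probs[c] * (1 - probs[c]) / n)
                assert abs(counts[c] / n - probs[c]) < 3 * se + 1e-9

    def test_zero_loadings_give_independent_items(self):
        spec = build_spec(
            n_groups=1, n_per_group=50_000, loadings=np.full(6, 1e-12),
            resid_corr={}, missing_rate=0.0,
        )
        ds = simulate_dataset(spec, seed=3)
        from ordinvar.polychoric import moments_and_weights

        mom = moments_and_weights(ds, ds.group_labels()[0])
        off = mom.corr[np.triu_indices(6, 1)]
        assert np.max(np.abs(off)) < 0.02

    def test_missingness_is_mcar(self):
        """Missing indicator uncorrelated with the latent trait at n = 1e5."""
        spec = build_spec(n_groups=1, n_per_group=100_000, missing_rate=0.05)
        ds = simulate_dataset(spec, seed=21)
        miss = np.isnan(ds.data[:, 0]).astype(float)
        r, _ = pearsonr(miss, ds.eta)
        assert abs(r) < 0.01

    def test_mar_mode_targets_rate_and_depends_on_eta(self):
        spec = build_spec(
            n_groups=1, n_per_group=50_000, missing_rate=0.05,
            missing_mode="mar", mar_slope=1.0,
        )
        ds = simulate_dataset(spec, seed=22)
        miss = np.isnan(ds.data[:, 0]).astype(float)
        assert abs(miss.mean() - 0.05) < 0.01
        r, _ = pearsonr(miss, ds.eta)
        assert r > 0.02  # higher trait -> more missing

    def test_group_label_exchangeability_under_invariance(self, invariant_spec):
        """All groups of an invariant DGP have the same category distribution
        (chi-square two-sample check between first and last group)."""
        ds = simulate_dataset(invariant_spec, seed=30)
        g1, g4 = ds.group_labels()[0], ds.group_labels()[-1]
        a = ds.group_data(g1)[:, 0]
        b = ds.group_data(g4)[:, 0]
        ca = np.bincount(a[~np.isnan(a)].astype(int), minlength=5)[1:]
        cb = np.bincount(b[~np.isnan(b)].astype(int), minlength=5)[1:]
        from scipy.stats import chi2_contingency

        _, p, _, _ = chi2_contingency(np.vstack([ca, cb]))
        assert p > 0.001


class TestInjectNoninvariance:
    def test_zero_shift_is_identity(self, invariant_spec):
        new = inject_noninvariance(invariant_spec, 5, "intercept", 0.0, ["g2"])
        assert new.params["g2"].intercepts[5] == invariant_spec.params["g2"].intercepts[5]

    def test_intercept_shift_is_local(self, invariant_spec):
        new = inject_noninvariance(invariant_spec, 5, "intercept", 0.3, ["g3", "g4"])
        for g in ("g1", "g2"):
            assert np.array_equal(new.params[g].intercepts, np.zeros(6))
        for g in ("g3", "g4"):
            expected = np.zeros(6)
            expected[5] = 0.3
            assert np.array_equal(new.params[g].intercepts, expected)
        assert new.provenance[-1]["item"] == 5
        # original untouched
        assert np.array_equal(invariant_spec.params["g3"].intercepts, np.zeros(6))

    def test_loading_shift_to_nonpositive_rejected(self, invariant_spec):
        with pytest.raises(ValueError, match="loading"):
            inject_noninvariance(invariant_spec, 0, "loading", -1.0, ["g2"])

    def test_threshold_shift_breaking_monotonicity_rejected(self, invariant_spec):
        with pytest.raises(ValueError, match="monotonicity"):
            inject_noninvariance(
                invariant_spec, 0, "threshold", np.array([2.0, 0.0, 0.0]), ["g2"]
            )

    def test_loading_shift_changes_item_trait_correlation_as_implied(self):
        """Observed item-trait polyserial-style correlation moves by the
        closed-form amount lam*sqrt(phi)/sqrt(lam^2 phi + theta)."""
        spec = build_spec(n_groups=2, n_per_group=50_000)
        shifted = inject_noninvariance(spec, 0, "loading", -0.25, ["g2"])
        ds = simulate_dataset(shifted, seed=17)
        from ordinvar.polychoric import moments_and_weights

        for g, lam0 in (("g1", 0.80), ("g2", 0.55)):
            p = shifted.params[g]
            mom = moments_and_weights(ds, g)
            # implied y*-correlation between items 1 and 2: lam1*lam2 / (sd1*sd2)
            sd1 = np.sqrt(p.loadings[0] ** 2 + p.theta[0])
            implied = p.loadings[0] * p.loadings[1] / (sd1 * 1.0)
            assert abs(mom.corr[0, 1] - implied) < 0.02


def test_dataset_roundtrip_to_frame(invariant_dataset):
    df = invariant_dataset.to_frame()
    assert df.shape == (8000, 7)
    back = OrdinalDataset(
        data=df[[f"item_{j+1}" for j in range(6)]].to_numpy(),
        groups=df["group"].to_numpy(),
        n_categories=4,
        item_names=invariant_dataset.item_names,
    )
    assert np.array_equal(back.data, invariant_dataset.data, equal_nan=True)
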