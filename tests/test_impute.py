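import numpy as np
import pytest

from hwmi import (
    MISSING,
    GenotypeVector,
    ImputationSpec,
    Panel,
    UnimputableError,
    convergence_trace,
    estimate_inbreeding,
    fit_multinomial_logit,
    impute_chained,
    impute_random,
    ld_r2,
    pool_imputed,
    select_covariates,
    tabulate,
)


def vec(mid, calls, pos):
    return GenotypeVector(mid, ("A", "B"), calls, pos=pos)


class TestLdR2:
    def test_self_and_flip_are_one(self):
        g1 = vec("a", [0, 1, 2, 0, 1, 2, 1], 1)
        g2 = vec("b", 2 - g1.calls, 2)
        assert ld_r2(g1, g1) == pytest.approx(1.0)
        assert ld_r2(g1, g2) == pytest.approx(1.0)

    def test_hand_computed_pairs(self):
        # dosage pairs (0,0),(1,1),(2,2),(0,1): Pearson r = 2/sqrt(5.5)
        g1 = vec("a", [0, 1, 2, 0], 1)
        g2 = vec("b", [0, 1, 2, 1], 2)
        expected = (2 / np.sqrt(5.5)) ** 2
        assert ld_r2(g1, g2) == pytest.approx(expected)
        assert ld_r2(g1, g2) == pytest.approx(
            np.corrcoef(g1.calls, g2.calls)[0, 1] ** 2
        )

    def test_uses_pairwise_complete_individuals(self):
        g1 = vec("a", [0, 1, 2, MISSING, 0], 1)
        g2 = vec("b", [0, 1, 2, 1, MISSING], 2)
        assert ld_r2(g1, g2) == pytest.approx(1.0)

    def test_no_variation_warns_and_returns_zero(self):
        g1 = vec("a", [1, 1, 1, 1], 1)
        g2 = vec("b", [0, 1, 2, 0], 2)
        with pytest.warns(UserWarning, match="no variation"):
            assert ld_r2(g1, g2) == 0.0


class TestSelectCovariates:
    def make_panel(self):
        rng = np.random.default_rng(5)
        base = rng.choice(3, size=200, p=[0.25, 0.5, 0.25]).astype(np.int8)
        noisy = base.copy()
        # flip some calls to lower r^2 by varying amounts
        def corrupt(arr, k, seed):
            out = arr.copy()
            r = np.random.default_rng(seed)
            idx = r.choice(len(arr), size=k, replace=False)
            out[idx] = r.choice(3, size=k)
            return out

        return Panel(
            individuals=[f"i{k}" for k in range(200)],
            markers=[
                vec("target", base, 1),
                vec("dup", base, 2),                      # r^2 = 1 duplicate
                vec("strong", corrupt(base, 15, 1), 3),
                vec("medium", corrupt(base, 60, 2), 4),
                vec("weak", corrupt(base, 160, 3), 5),
            ],
        )

    def test_threshold_ordering_and_duplicate_exclusion(self):
        panel = self.make_panel()
        spec = ImputationSpec(target="target", ld_threshold=0.5)
        selected, fallback = select_covariates("target", panel, spec)
        assert "dup" not in selected          # perfect duplicate excluded
        assert selected[0] == "strong"
        assert "weak" not in selected
        assert not fallback

    def test_intensity_fallback_when_nothing_passes(self):
        panel = self.make_panel()
        panel.intensities["target"] = np.zeros((200, 2))
        spec = ImputationSpec(target="target", ld_threshold=0.999)
        selected, fallback = select_covariates("target", panel, spec)
        assert selected == []
        assert fallback


class TestMultinomialLogit:
    def test_intercept_only_reproduces_marginal(self):
        y = np.array([0] * 50 + [1] * 30 + [2] * 20)
        fit = fit_multinomial_logit(y, np.empty((100, 0)))
        probs = fit.predict_proba(np.empty((1, 0)))[0]
        np.testing.assert_allclose(probs, [0.5, 0.3, 0.2], atol=1e-6)
        assert fit.reference == 0  # most frequent category

    def test_binary_case_matches_statsmodels_logit(self):
        """With two categories the fit is binary logistic regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.normal(size=120)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = (rng.random(120) < p).astype(int) * 2  # categories {0, 2}
        fit = fit_multinomial_logit(y, x, ridge=1e-10)
        # the single non-reference row models log P(nonref)/P(ref)
        ref_fit = sm.Logit(
            (y != fit.reference).astype(float), sm.add_constant(x)
        ).fit(disp=0)
        np.testing.assert_allclose(fit.coef[0], ref_fit.params, atol=1e-4)

    def test_perfect_separation_converges_with_ridge(self):
        x = np.r_[np.zeros(30), np.ones(30)]
        y = np.r_[np.zeros(30), np.full(30, 2)].astype(int)
        fit = fit_multinomial_logit(y, x, ridge=1e-4)
        p0 = fit.predict_proba(np.array([[0.0]]))[0]
        p1 = fit.predict_proba(np.array([[1.0]]))[0]
        assert p0[list(fit.categories).index(0)] > 0.99
        assert p1[list(fit.categories).index(2)] > 0.99

    def test_single_category_rejected(self):
        with pytest.raises(UnimputableError):
            fit_multinomial_logit(np.zeros(10, int), np.empty((10, 0)))

    def test_coefficient_draws_have_plausible_spread(self):
        rng = np.random.default_rng(9)
        y = rng.choice(3, size=300, p=[0.3, 0.4, 0.3])
        x = rng.normal(size=300)
        fit = fit_multinomial_logit(y, x)
        draws = np.array([fit.sample_coef(np.random.default_rng(s)).ravel()
                          for s in range(400)])
        sd_theory = np.sqrt(np.diag(fit.cov))
        np.testing.assert_allclose(draws.std(axis=0), sd_theory, rtol=0.25)


def gt_panel(gt_vector):
    return Panel(
        individuals=[f"i{k}" for k in range(146)], markers=[gt_vector]
    )


class TestImputeRandom:
    def test_no_missings_is_identity(self):
        g = vec("m", [0, 1, 2, 1], 1)
        imp = impute_random(g, m=3, seed=0)
        for i in range(3):
            np.testing.assert_array_equal(
                imp.marker_calls(i, "m"), g.calls
            )

    def test_category_restriction(self):
        g = vec("m", [0] * 10 + [2] * 10 + [MISSING] * 10, 1)
        imp = impute_random(g, m=5, seed=1)
        for i in range(5):
            assert not (imp.marker_calls(i, "m") == 1).any()

    def test_all_missing_rejected(self):
        with pytest.raises(UnimputableError):
            impute_random(vec("m", [MISSING] * 4, 1), m=2, seed=0)

    def test_pooled_estimate_near_complete_case(self, gt_vector):
        imp = impute_random(gt_vector, m=50, seed=2)
        res = pool_imputed(imp, "gt_snp")
        assert res.q_bar == pytest.approx(0.30, abs=0.03)

    def test_reproducible(self, gt_vector):
        a = impute_random(gt_vector, m=5, seed=33)
        b = impute_random(gt_vector, m=5, seed=33)
        for i in range(5):
            np.testing.assert_array_equal(a.calls[i], b.calls[i])


def mnar_block_panel(seed, n=150, r2=0.85):
    """Two-marker LD block; heterozygote-biased deletion on the first."""
    from hwmi import PanelConfig, gen_genotypes, gen_intensities

    cfg = PanelConfig(n_individuals=n, n_markers=0, ld_blocks=[(2, r2)],
                      seed=seed)
    panel = gen_genotypes(cfg)
    gen_intensities(panel, cfg)
    complete = panel.copy()
    g = panel.markers[0]
    rng = np.random.default_rng(seed + 10_000)
    pi = np.array([0.05, 0.75, 0.05])[g.calls]
    g.calls = np.where(rng.random(n) < pi, MISSING, g.calls).astype(np.int8)
    return panel, complete


class TestImputeChained:
    def test_observed_entries_immutable_and_reproducible(self):
        panel, _ = mnar_block_panel(1)
        target = panel.marker_ids[0]
        spec = ImputationSpec(target=target, m=4, iterations=3, seed=5)
        imp1 = impute_chained(panel, spec)
        imp2 = impute_chained(panel, spec)
        base = panel.call_matrix()
        obs = base != MISSING
        for i in range(4):
            np.testing.assert_array_equal(imp1.calls[i][obs], base[obs])
            np.testing.assert_array_equal(imp1.calls[i], imp2.calls[i])

    def test_unobserved_category_never_imputed(self):
        # AB never observed at the target -> never imputed; f -> 1
        calls = np.array([0] * 80 + [2] * 6 + [MISSING] * 14, dtype=np.int8)
        panel = Panel(
            individuals=[f"i{k}" for k in range(100)],
            markers=[vec("t", calls, 1)],
        )
        spec = ImputationSpec(target="t", m=10, iterations=2, seed=8)
        imp = impute_chained(panel, spec)
        for i in range(10):
            assert not (imp.marker_calls(i, "t") == 1).any()
        res = pool_imputed(imp, "t")
        assert res.q_bar > 0.9

    def test_single_observed_category_unimputable(self):
        calls = np.array([0] * 90 + [MISSING] * 10, dtype=np.int8)
        panel = Panel(
            individuals=[f"i{k}" for k in range(100)],
            markers=[vec("t", calls, 1)],
        )
        with pytest.raises(UnimputableError):
            impute_chained(panel, ImputationSpec(target="t", m=3, seed=0))

    def test_covariate_recovers_mnar_target(self):
        """Heterozygote-biased deletion: a linked covariate pulls the pooled
        estimate back toward the complete-data value."""
        wins = 0
        for s in range(8):
            panel, complete = mnar_block_panel(40 + s)
            target = panel.marker_ids[0]
            f_complete = estimate_inbreeding(
                tabulate(complete.markers[0])
            ).f_hat
            f_discard = estimate_inbreeding(tabulate(panel.markers[0])).f_hat
            spec = ImputationSpec(target=target, m=8, iterations=4,
                                  seed=60 + s, use_intensities=False)
            res = pool_imputed(impute_chained(panel, spec), target)
            wins += abs(res.q_bar - f_complete) < abs(f_discard - f_complete)
        assert wins >= 7

    def test_convergence_trace_shape_and_between_variance(self):
        panel, _ = mnar_block_panel(77)
        target = panel.marker_ids[0]
        spec = ImputationSpec(target=target, m=12, iterations=6, seed=9,
                              use_intensities=False)
        imp = impute_chained(panel, spec)
        trace = convergence_trace(imp, target)
        assert trace.shape == (12, 6)
        # final iterates are the pooled estimates
        res = pool_imputed(imp, target)
        final = trace[:, -1]
        assert final.mean() == pytest.approx(res.q_bar, abs=1e-9)
        assert final.var(ddof=1) == pytest.approx(res.b, rel=1e-9)
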