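import numpy as np
import pytest

from hwmi import (
    MISSING,
    MissingnessRegime,
    PanelConfig,
    apply_missingness,
    estimate_inbreeding,
    gen_genotypes,
    gen_intensities,
    ld_r2,
    tabulate,
)


class TestGenGenotypes:
    def test_hwp_marker_frequencies(self):
        cfg = PanelConfig(n_individuals=20000, n_markers=1, maf=0.5, f=0.0,
                          seed=0)
        c = tabulate(gen_genotypes(cfg).markers[0])
        n = c.n
        # 3-sigma multinomial bands around (0.25, 0.5, 0.25)
        for obs, exp in zip(c.as_tuple(), (0.25, 0.5, 0.25)):
            assert abs(obs / n - exp) < 3 * np.sqrt(exp * (1 - exp) / n)

    def test_full_inbreeding_has_no_heterozygotes(self):
        cfg = PanelConfig(n_individuals=500, n_markers=3, maf=0.3, f=1.0,
                          seed=1)
        panel = gen_genotypes(cfg)
        for g in panel.markers:
            assert tabulate(g).n_AB == 0

    def test_infeasible_maf_f_pair_rejected(self):
        cfg = PanelConfig(n_individuals=10, n_markers=1, maf=0.2, f=-0.9)
        with pytest.raises(ValueError, match="admissible"):
            gen_genotypes(cfg)

    def test_estimator_recovers_configured_f(self):
        """Parameter recovery: mean bias within 3 Monte-Carlo SE."""
        f_true, reps, n = 0.15, 200, 1000
        ests = []
        for s in range(reps):
            cfg = PanelConfig(n_individuals=n, n_markers=1, maf=0.3,
                              f=f_true, seed=s)
            ests.append(
                estimate_inbreeding(tabulate(gen_genotypes(cfg).markers[0])).f_hat
            )
        ests = np.array(ests)
        bias = ests.mean() - f_true
        assert abs(bias) < 3 * ests.std(ddof=1) / np.sqrt(reps)

    def test_ld_block_hits_target_r2(self):
        cfg = PanelConfig(n_individuals=2000, n_markers=0,
                          ld_blocks=[(3, 0.8)], seed=2)
        panel = gen_genotypes(cfg)
        r2 = ld_r2(panel.markers[0], panel.markers[1])
        assert r2 == pytest.approx(0.8, abs=0.1)
        # block loci are themselves near HWP (f = 0)
        for g in panel.markers:
            f = estimate_inbreeding(tabulate(g)).f_hat
            assert abs(f) < 0.1


class TestGenIntensities:
    def test_zero_noise_gives_exact_centroids(self):
        cfg = PanelConfig(n_individuals=50, n_markers=1, maf=0.4, f=0.0,
                          intensity_sd=0.0, seed=3)
        panel = gen_genotypes(cfg)
        gen_intensities(panel, cfg)
        g = panel.markers[0]
        means = {0: (2.0, 0.2), 1: (1.1, 1.1), 2: (0.2, 2.0)}
        for k, call in enumerate(g.calls):
            np.testing.assert_allclose(
                panel.intensities[g.marker_id][k], means[int(call)]
            )

    def test_default_clouds_are_linearly_separable(self):
        from sklearn.linear_model import LogisticRegression

        cfg = PanelConfig(n_individuals=600, n_markers=1, maf=0.4, f=0.0,
                          seed=4)
        panel = gen_genotypes(cfg)
        gen_intensities(panel, cfg)
        g = panel.markers[0]
        X = panel.intensities[g.marker_id]
        clf = LogisticRegression(max_iter=1000).fit(X, g.calls)
        assert clf.score(X, g.calls) > 0.95

    def test_swapping_homozygote_means_flips_channels(self):
        means = {0: (0.2, 2.0), 1: (1.1, 1.1), 2: (2.0, 0.2)}
        cfg = PanelConfig(n_individuals=50, n_markers=1, maf=0.4, f=0.0,
                          intensity_means=means, intensity_sd=0.0, seed=5)
        panel = gen_genotypes(cfg)
        gen_intensities(panel, cfg)
        g = panel.markers[0]
        hom_a = panel.intensities[g.marker_id][g.calls == 0]
        if len(hom_a):
            assert (hom_a[:, 1] > hom_a[:, 0]).all()


class TestApplyMissingness:
    def test_zero_probability_is_identity(self):
        cfg = PanelConfig(n_individuals=100, n_markers=4, seed=6)
        panel = gen_genotypes(cfg)
        deg = apply_missingness(panel, MissingnessRegime("MCAR", 0.0, seed=7))
        np.testing.assert_array_equal(deg.panel.call_matrix(), deg.truth)
        assert deg.missing_rate == 0.0

    def test_truth_agrees_on_nonmissing_entries(self):
        cfg = PanelConfig(n_individuals=200, n_markers=6, seed=8)
        panel = gen_genotypes(cfg)
        regime = MissingnessRegime("MNAR", (0.1, 0.5, 0.1), snp_fraction=0.5,
                                   seed=9)
        deg = apply_missingness(panel, regime)
        mat = deg.panel.call_matrix()
        obs = mat != MISSING
        np.testing.assert_array_equal(mat[obs], deg.truth[obs])
        assert len(deg.affected) == 3

    def test_per_genotype_deletion_rates(self):
        cfg = PanelConfig(n_individuals=30000, n_markers=1, maf=0.4, f=0.0,
                          seed=10)
        panel = gen_genotypes(cfg)
        probs = (0.05, 0.75, 0.05)
        deg = apply_missingness(
            panel, MissingnessRegime("MNAR", probs, seed=11)
        )
        truth = deg.truth[:, 0]
        mat = deg.panel.call_matrix()[:, 0]
        for g_code, pi in enumerate(probs):
            sel = truth == g_code
            rate = (mat[sel] == MISSING).mean()
            assert abs(rate - pi) < 3 * np.sqrt(pi * (1 - pi) / sel.sum())

    def test_mcar_overall_rate_table_style(self):
        # deletion prob 0.25 on 25% of markers -> ~6% missing overall
        cfg = PanelConfig(n_individuals=400, n_markers=40, seed=12)
        panel = gen_genotypes(cfg)
        regime = MissingnessRegime("MCAR", 0.25, snp_fraction=0.25, seed=13)
        deg = apply_missingness(panel, regime)
        assert deg.missing_rate == pytest.approx(0.0625, abs=0.015)

    def test_mnar_het_deletion_analytic_complete_case_bias(self):
        """Brute-force oracle for the reweighting formula: deleting
        heterozygotes with probability 0.75 from an HWP marker at maf 0.2
        biases the complete-case f_hat to about 0.4255."""
        p, probs = 0.2, np.array([0.05, 0.75, 0.05])
        freqs = np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
        post = freqs * (1 - probs)
        post /= post.sum()
        p_prime = post[0] + post[1] / 2
        f_analytic = 1 - post[1] / (2 * p_prime * (1 - p_prime))
        assert f_analytic == pytest.approx(0.4255, abs=5e-4)
        cfg = PanelConfig(n_individuals=60000, n_markers=1, maf=p, f=0.0,
                          seed=14)
        panel = gen_genotypes(cfg)
        deg = apply_missingness(
            panel, MissingnessRegime("MNAR", tuple(probs), seed=15)
        )
        f_sim = estimate_inbreeding(tabulate(deg.panel.markers[0])).f_hat
        assert f_sim == pytest.approx(f_analytic, abs=0.02)

    def test_mar_intensity_concentrates_on_boundaries(self):
        cfg = PanelConfig(n_individuals=3000, n_markers=1, maf=0.4, f=0.0,
                          seed=16)
        panel = gen_genotypes(cfg)
        gen_intensities(panel, cfg)
        regime = MissingnessRegime("MAR-intensity", 0.5, seed=17)
        deg = apply_missingness(panel, regime)
        g = deg.panel.markers[0]
        intens = deg.panel.intensities[g.marker_id]
        truth = deg.truth[:, 0]
        cents = np.array([intens[truth == c].mean(axis=0) for c in range(3)])
        d = np.min(np.linalg.norm(intens[:, None] - cents[None], axis=2),
                   axis=1)
        mis = g.missing_mask
        assert mis.sum() > 15
        assert d[mis].mean() > d[~mis].mean()
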