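"""Empirical-gamma screen simulator: moments, determinism, dispersion fits."""
import numpy as np
import pytest
from scipy.stats import ks_2samp

from crisphi import SimSpec, build_benchmark, fit_template_dispersions, sample_master, simulate_screen
from crisphi.simulate import dispersion_objective, screen_summary_stats, synthetic_master_fractions


def _spec(n_guides=4, n_samples=3, phi=0.0, eps=1.0, m=None, seed=0, **kw):
    n_genes = n_guides  # one guide per gene unless overridden
    m = np.full(n_guides, 1.0 / n_guides) if m is None else m
    defaults = dict(
        sigma_m=m.mean() / 0.2**2,
        sigma_x=m.mean() / 0.1**2,
        sigma_y=m.mean() / 0.1**2,
        depth_initial=300.0 * n_guides,
        depth_final=300.0 * n_guides,
    )
    defaults.update(kw)
    return SimSpec(
        master_fractions=m,
        gene_index=np.arange(n_guides) % n_genes,
        phi_by_gene=np.full(n_genes, phi),
        epsilon_by_guide=np.full(n_guides, eps),
        n_samples=n_samples,
        seed=seed,
        **defaults,
    )


class TestSimulateScreen:
    def test_infection_draw_mean_matches_master_fraction(self):
        # shape-scale algebra: E[mu] = (sigma/m)(m^2/sigma) = m
        spec = _spec(n_guides=2, n_samples=4000, m=np.array([0.3, 0.7]), seed=1)
        _, _, truth = simulate_screen(spec)
        mu = truth["mu_hat"]
        for g, m in enumerate([0.3, 0.7]):
            se = mu[:, g].std() / np.sqrt(mu.shape[0])
            assert abs(mu[:, g].mean() - m) < 3 * se

    def test_complete_knockout_gives_zero_final_counts(self):
        spec = _spec(phi=1.0, eps=1.0, seed=2)
        _, y, _ = simulate_screen(spec)
        assert np.all(y == 0)

    def test_initial_count_mean_matches_target_depth(self):
        # m = 0.001 at depth 3e5: mean initial count should be 300
        m = np.full(1000, 0.001)
        spec = _spec(n_guides=1000, n_samples=10, m=m, seed=3,
                     depth_initial=3e5, depth_final=3e5)
        x, _, _ = simulate_screen(spec)
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - 300.0) < 3 * se

    def test_identical_seed_is_bit_identical(self):
        x1, y1, _ = simulate_screen(_spec(seed=9))
        x2, y2, _ = simulate_screen(_spec(seed=9))
        assert np.array_equal(x1, x2) and np.array_equal(y1, y2)

    def test_zero_master_fraction_warns_and_zeroes(self):
        m = np.array([0.0, 1.0])
        with pytest.warns(UserWarning, match="zero master fraction"):
            x, y, _ = simulate_screen(_spec(n_guides=2, m=m, seed=4))
        assert np.all(x[:, 0] == 0) and np.all(y[:, 0] == 0)

    def test_counts_are_nonnegative_integers(self):
        x, y, _ = simulate_screen(_spec(seed=5))
        assert x.dtype == np.int64 and y.dtype == np.int64
        assert x.min() >= 0 and y.min() >= 0

    def test_mean_preservation_in_low_noise_limit(self):
        # E[y]/E[x] -> (Y/X)(1 - eps*phi) as the gamma noise shrinks
        m = np.full(200, 1 / 200)
        spec = _spec(
            n_guides=200, n_samples=30, m=m, phi=0.5, eps=0.8, seed=6,
            sigma_m=m.mean() * 1e4, sigma_x=m.mean() * 1e4, sigma_y=m.mean() * 1e4,
            depth_initial=1e6, depth_final=2e6,
        )
        x, y, _ = simulate_screen(spec)
        ratio = y.mean() / x.mean()
        assert ratio == pytest.approx(2.0 * (1 - 0.8 * 0.5), rel=0.02)


class TestSampleMaster:
    def test_equal_template_gives_uniform_fractions(self):
        out = sample_master(np.full(50, 7), n_guides=20, seed=0)
        assert out == pytest.approx(np.full(20, 1 / 20))

    def test_sums_to_one(self):
        rng = np.random.default_rng(7)
        out = sample_master(rng.integers(1, 1000, 500), n_guides=333, seed=1)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_distributional_fidelity(self):
        rng = np.random.default_rng(8)
        template = rng.lognormal(0, 1.0, size=5000)
        out = sample_master(template, n_guides=10_000, seed=2)
        tf = template / template.sum()
        # compare shapes of the log-fraction distributions
        stat = ks_2samp(np.log(out * out.size), np.log(tf * tf.size)).statistic
        assert stat <= 0.05

    def test_empty_template_is_an_error(self):
        with pytest.raises(ValueError):
            sample_master(np.array([]), 10)

    def test_without_replacement_needs_large_template(self):
        with pytest.raises(ValueError):
            sample_master(np.arange(1, 5), 10, replace=False)


class TestDispersionFitting:
    def test_round_trip_recovery_within_factor_two(self):
        G = 600
        m = synthetic_master_fractions(G, seed=71)
        true = (m.mean() / 0.2**2, m.mean() / 0.1**2, m.mean() / 0.12**2)
        spec = SimSpec(
            master_fractions=m,
            gene_index=np.arange(G),
            phi_by_gene=np.zeros(G),
            epsilon_by_guide=np.ones(G),
            sigma_m=true[0], sigma_x=true[1], sigma_y=true[2],
            depth_initial=300.0 * G, depth_final=300.0 * G,
            n_samples=3, seed=72,
        )
        x, y, _ = simulate_screen(spec)
        est = fit_template_dispersions(x, y, template_master=m, seed=73)
        for got, want in zip(est, true):
            assert want / 2 <= got <= want * 2

    def test_objective_prefers_truth_over_perturbation(self):
        G = 400
        m = np.full(G, 1 / G)
        sig = (m.mean() / 0.2**2, m.mean() / 0.1**2, m.mean() / 0.1**2)
        spec = SimSpec(
            master_fractions=m, gene_index=np.arange(G),
            phi_by_gene=np.zeros(G), epsilon_by_guide=np.ones(G),
            sigma_m=sig[0], sigma_x=sig[1], sigma_y=sig[2],
            depth_initial=300.0 * G, depth_final=300.0 * G,
            n_samples=3, seed=74,
        )
        x, y, _ = simulate_screen(spec)
        stats = screen_summary_stats(x, y)
        args = (stats, m, 300.0 * G, 300.0 * G, 3, 75)
        at_truth = dispersion_objective(np.log(sig), *args)
        perturbed = dispersion_objective(np.log(np.array(sig) * 10), *args)
        assert at_truth <= perturbed

    def test_identical_replicates_push_dispersion_up(self):
        # a noise-free template: simulated CV must shrink toward 0, so the
        # objective decreases as the dispersions grow
        G = 300
        m = np.full(G, 1 / G)
        rng = np.random.default_rng(76)
        row_x = rng.integers(250, 350, G)
        row_y = rng.integers(250, 350, G)
        x = np.vstack([row_x, row_x, row_x])
        y = np.vstack([row_y, row_y, row_y])
        stats = screen_summary_stats(x, y)
        args = (stats, m, float(x.sum(1).mean()), float(y.sum(1).mean()), 3, 77)
        low = dispersion_objective(np.log([m.mean() / 0.1, m.mean() / 0.1, m.mean() / 0.1]), *args)
        high = dispersion_objective(np.log([m.mean() * 1e4, m.mean() * 1e4, m.mean() * 1e4]), *args)
        assert high < low

    def test_single_replicate_is_an_error(self):
        with pytest.raises(ValueError, match="replicates"):
            fit_template_dispersions(np.ones((1, 10)), np.ones((1, 10)))


class TestBuildBenchmark:
    def test_absolute_full_scale_layout(self):
        ds, lib, truth, neg = build_benchmark("absolute", seed=0, scale=1.0)
        assert len(truth) == 5250
        assert (truth["gene_class"] == "null").sum() == 3150
        assert (truth["phi_test"] == 0.99).sum() == 600
        assert len(neg) == 300
        assert ds.n_guides == 5250 * 4
        assert ds.n_samples == 3

    def test_differential_full_scale_layout(self):
        ds, lib, truth, neg = build_benchmark(
            "differential", level_values=(0.2,), seed=0, scale=1.0
        )
        diff = truth["gene_class"] == "differential_0.2"
        assert diff.sum() == 300
        assert (truth["gene_class"] == "null").sum() == 3150
        assert np.all(truth.loc[diff, "phi_control"] == 0.0)
        assert ds.n_samples == 6
        assert sorted(set(ds.panel_labels)) == ["control", "test"]

    def test_scaling_preserves_proportions(self):
        _, _, truth, _ = build_benchmark("absolute", seed=0, scale=0.1)
        assert (truth["gene_class"] == "null").sum() == 315
        assert (truth["phi_test"] == 0.99).sum() == 60

    def test_unknown_design_is_an_error(self):
        with pytest.raises(ValueError):
            build_benchmark("sideways")

    def test_levels_above_one_rejected(self):
        with pytest.raises(ValueError):
            build_benchmark("absolute", level_values=(1.2,))
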