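"""Fitting, likelihood-ratio tests, and empirical p-values."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from crisphi import (
    EssentialityModel,
    FitConfig,
    GuideLibrary,
    LikelihoodOptions,
    ScreenDataset,
    SimSpec,
    adjust_pvalues,
    empirical_pvalues,
    simulate_screen,
    simulated_null_statistics,
)


class TestEmpiricalPvalues:
    def test_statistic_above_every_null(self):
        null = np.arange(99, dtype=float)
        p = empirical_pvalues([1000.0], null)
        assert p[0] == pytest.approx(1 / 100)

    def test_statistic_at_null_median(self):
        null = np.arange(99, dtype=float)  # median is 49
        p = empirical_pvalues([49.0], null)
        assert p[0] == pytest.approx(0.5, abs=0.02)

    def test_plugin_can_reach_zero(self):
        p = empirical_pvalues([1000.0], np.arange(99.0), smoothing="plugin")
        assert p[0] == 0.0

    def test_monotone_nonincreasing_in_statistic(self):
        rng = np.random.default_rng(8)
        null = rng.normal(size=200)
        T = np.sort(rng.normal(size=50))
        p = empirical_pvalues(T, null)
        assert np.all(np.diff(p) <= 0)

    def test_self_application_is_approximately_uniform(self):
        rng = np.random.default_rng(9)
        null = rng.normal(size=300)
        p = empirical_pvalues(null, null)
        assert kstest(p, "uniform").statistic < 0.1

    def test_empty_null_is_an_error(self):
        with pytest.raises(ValueError):
            empirical_pvalues([1.0], [])

    def test_small_null_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            empirical_pvalues([1.0], np.arange(5.0))


class TestAdjustPvalues:
    def test_bonferroni(self):
        assert adjust_pvalues([0.001], n_tests=10)[0] == pytest.approx(0.01)
        assert adjust_pvalues([0.5], n_tests=10)[0] == 1.0

    def test_vector_matches_scalar(self):
        p = np.array([0.001, 0.5, 0.02])
        out = adjust_pvalues(p)
        assert out == pytest.approx([min(1, v * 3) for v in p])


def _make_dataset(x, y, m, c, genes, gc=None, panels=None):
    G = y.shape[1]
    guides = np.array([f"sg{i}" for i in range(G)], dtype=object)
    ds = ScreenDataset(
        guide_ids=guides,
        gene_of_guide=np.asarray(genes, dtype=object),
        x_counts=x,
        y_counts=y,
        master_fractions=m,
        cells_infected=np.full(y.shape[0], c),
        panel_labels=None if panels is None else np.asarray(panels, dtype=object),
    )
    lib = GuideLibrary(
        guide_ids=guides,
        gene_of_guide=np.asarray(genes, dtype=object),
        gc_fraction=np.full(G, 0.5) if gc is None else np.asarray(gc, float),
    )
    return ds, lib


EXACT = LikelihoodOptions(summation_mode="exact")


class TestFit:
    def test_no_depletion_signal_gives_phi_near_zero(self):
        # final counts equal initial counts and both match the prior mean
        # (x = gamma * c * m): no depletion signal.  The MLE is zero up to
        # a small offset of order 1/counts: posterior shrinkage of the
        # latent cell count and Poisson skewness shift it slightly, so
        # exact zero holds only in the large-count limit.
        x = np.full((1, 4), 50)
        ds, lib = _make_dataset(x, x.copy(), np.full(4, 0.1), 500,
                                ["A", "A", "B", "B"])
        res = EssentialityModel(ds, lib, options=EXACT).fit()
        assert res.phi_hat["A"] == pytest.approx(0.0, abs=0.01)
        assert res.phi_hat["B"] == pytest.approx(0.0, abs=0.01)

    def test_null_screen_recovery_and_nesting(self, null_screen_fit):
        res, truth = null_screen_fit
        # simulated with eps = 1, phi = 0 everywhere: median phi_hat near 0
        assert abs(np.median(res.phi_hat.to_numpy())) < 0.05
        # nesting: T >= 0 for every gene, by construction of the fit
        assert np.all(res.gene_results["llr"].to_numpy() >= 0)
        # coordinate ascent never decreases the total log-likelihood
        assert np.all(np.diff(res.loglik_path) >= -1e-6)

    def test_strongly_depleted_gene_scores_high_llr(self, tiny_screen_fit):
        res, truth = tiny_screen_fit
        g = res.gene_results.join(truth["gene_class"])
        strong = g.loc[g.gene_class == "phi_0.99", "llr"].min()
        null_max = g.loc[g.gene_class == "null", "llr"].max()
        assert strong > null_max

    def test_pvalues_attached_and_valid(self, tiny_screen_fit):
        res, _ = tiny_screen_fit
        p = res.gene_results["p_empirical"]
        assert ((p >= 0) & (p <= 1)).all()
        assert ((res.gene_results["p_adjusted"] >= p - 1e-12)).all()

    def test_summary_mentions_convergence(self, tiny_screen_fit):
        res, _ = tiny_screen_fit
        text = res.summary()
        assert "converged" in text
        assert "phi_hat" in text


@pytest.fixture(scope="module")
def null_screen_fit():
    """300 nonessential genes, fully efficient guides, 3 replicates."""
    from crisphi.simulate import synthetic_master_fractions

    n_genes, gpg = 300, 4
    G = n_genes * gpg
    m = synthetic_master_fractions(G, seed=31)
    spec = SimSpec(
        master_fractions=m,
        gene_index=np.repeat(np.arange(n_genes), gpg),
        phi_by_gene=np.zeros(n_genes),
        epsilon_by_guide=np.ones(G),
        sigma_m=m.mean() / 0.2**2,
        sigma_x=m.mean() / 0.1**2,
        sigma_y=m.mean() / 0.1**2,
        depth_initial=300.0 * G,
        depth_final=300.0 * G,
        n_samples=3,
        seed=32,
    )
    x, y, _ = simulate_screen(spec)
    genes = [f"g{j:04d}" for j in np.repeat(np.arange(n_genes), gpg)]
    ds, lib = _make_dataset(x, y, None, round(200 * G), genes,
                            gc=np.random.default_rng(33).uniform(0, 1, G))
    model = EssentialityModel(ds, lib, negative_controls={f"g{j:04d}" for j in range(50)})
    res = model.fit()
    return res, None


@pytest.fixture(scope="module")
def tiny_screen_fit(tiny_screen):
    ds, lib, truth, neg = tiny_screen
    model = EssentialityModel(ds, lib, negative_controls=neg)
    return model.fit(), truth


@pytest.fixture(scope="module")
def differential_toy():
    """Two panels with identical count tables for every gene."""
    rng = np.random.default_rng(41)
    G = 40
    genes = [f"g{j}" for j in np.repeat(np.arange(G // 4), 4)]
    m = np.full(G, 1 / G)
    c = 200 * G
    n = rng.poisson(c / G, size=(1, G))
    x_half = rng.poisson(1.0 * n)
    y_half = rng.poisson(1.0 * n)
    x = np.vstack([x_half, x_half])
    y = np.vstack([y_half, y_half])
    ds, lib = _make_dataset(x, y, m, c, genes, panels=["test", "control"])
    model = EssentialityModel(ds, lib, reference="all")
    return model.fit()


class TestDifferential:
    def test_identical_panels_give_zero_statistic(self, differential_toy):
        diff = differential_toy.differential()
        assert np.allclose(diff.gene_results["llr"], 0.0, atol=1e-3)
        assert diff.gene_results["phi_test"].to_numpy() == pytest.approx(
            diff.gene_results["phi_control"].to_numpy(), abs=5e-3
        )

    def test_one_sided_gate_zeroes_wrong_direction(self):
        # control panel depleted (phi_c = 0.99), test panel untouched:
        # a one-sided test for phi_t > phi_c must return exactly 0
        rng = np.random.default_rng(42)
        G = 40
        genes = [f"g{j}" for j in np.repeat(np.arange(G // 4), 4)]
        m = np.full(G, 1 / G)
        c = 200 * G
        n = rng.poisson(c / G, size=(2, G))
        x = rng.poisson(1.0 * n)
        y = x.copy()
        y[1] = rng.poisson(0.05 * n[1])  # control panel strongly depleted
        ds, lib = _make_dataset(x, y, m, c, genes, panels=["test", "control"])
        res = EssentialityModel(ds, lib, reference="all").fit()
        diff = res.differential(one_sided=True)
        # scaling absorbs a global shift, but every gene's phi_t <= phi_c
        gate = diff.gene_results
        assert np.all(gate.loc[gate.phi_test <= gate.phi_control, "llr"] == 0.0)

    def test_missing_panel_is_an_error(self, tiny_screen_fit):
        res, _ = tiny_screen_fit
        with pytest.raises(ValueError, match="test"):
            res.differential()

    def test_differential_nesting_holds(self, differential_fit):
        diff, truth = differential_fit
        assert np.all(diff.gene_results["llr"].to_numpy() >= 0)

    def test_differential_genes_outrank_uniform_essentials(self, differential_fit):
        diff, truth = differential_fit
        g = diff.gene_results.join(truth["gene_class"])
        auc_pool = g.loc[g.gene_class.str.startswith("differential"), "llr"]
        uniform = g.loc[g.gene_class == "uniform_0.5", "llr"]
        from crisphi.benchmark import mann_whitney_auc

        assert mann_whitney_auc(auc_pool, uniform) >= 0.9


@pytest.fixture(scope="module")
def differential_fit():
    from crisphi.simulate import build_benchmark

    ds, lib, truth, neg = build_benchmark(
        "differential", level_values=(0.6,), seed=51, scale=0.03
    )
    model = EssentialityModel(ds, lib, negative_controls=neg)
    res = model.fit()
    return res.differential(), truth


class TestEfficiencyRecovery:
    def test_two_cluster_efficiency_ordering(self):
        """Two GC clusters with true efficiency 0.95 and 0.5: the fitted
        per-decile efficiencies are ordered correctly and within 0.15."""
        from crisphi.simulate import synthetic_master_fractions

        rng = np.random.default_rng(61)
        n_genes, gpg = 240, 4
        G = n_genes * gpg
        gc = np.where(rng.uniform(size=G) < 0.5, 0.3, 0.7)
        eps_true = np.where(gc < 0.5, 0.95, 0.5)
        phi = np.where(np.arange(n_genes) < 120, 0.7, 0.0)
        m = synthetic_master_fractions(G, seed=62)
        spec = SimSpec(
            master_fractions=m,
            gene_index=np.repeat(np.arange(n_genes), gpg),
            phi_by_gene=phi,
            epsilon_by_guide=eps_true,
            sigma_m=m.mean() / 0.2**2,
            sigma_x=m.mean() / 0.1**2,
            sigma_y=m.mean() / 0.1**2,
            depth_initial=300.0 * G,
            depth_final=300.0 * G,
            n_samples=3,
            seed=63,
        )
        x, y, _ = simulate_screen(spec)
        genes = [f"g{j:04d}" for j in np.repeat(np.arange(n_genes), gpg)]
        ds, lib = _make_dataset(x, y, None, round(200 * G), genes, gc=gc)
        neg = {f"g{j:04d}" for j in range(120, 180)}
        model = EssentialityModel(ds, lib, negative_controls=neg)
        res = model.fit()
        bins_low = np.unique(model.feature_bins[model.gc < 0.5])
        bins_high = np.unique(model.feature_bins[model.gc > 0.5])
        eps_by_bin = res.state.epsilon_by_bin
        eps_low = float(np.mean(eps_by_bin[bins_low]))
        eps_high = float(np.mean(eps_by_bin[bins_high]))
        assert eps_low > eps_high
        assert eps_low == pytest.approx(0.95, abs=0.15)
        assert eps_high == pytest.approx(0.5, abs=0.15)


class TestSimulatedNull:
    def test_returns_nonnegative_statistics(self, differential_fit_parent):
        stats = simulated_null_statistics(differential_fit_parent, n_genes=20, seed=5)
        assert stats.shape == (20,)
        assert np.all(stats >= 0)


@pytest.fixture(scope="module")
def differential_fit_parent():
    from crisphi.simulate import build_benchmark

    ds, lib, truth, neg = build_benchmark(
        "differential", level_values=(0.6,), seed=52, scale=0.01
    )
    return EssentialityModel(ds, lib, negative_controls=neg).fit()
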