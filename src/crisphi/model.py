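"""Maximum-likelihood estimation of gene essentiality and LRT machinery.

:class:`EssentialityModel` wraps a :class:`~crisphi.data.ScreenDataset`
plus a guide library, fixes the sample scaling factors by
median-of-ratios normalization, and fits the per-gene essentiality
phi_G and the per-decile guide-efficiency weights omega by coordinate
ascent: with omega held fixed the likelihood decomposes by gene, and
with phi held fixed it decomposes by efficiency feature (the one-hot
design), so each coordinate is a bounded one-dimensional maximization
(Brent-type).  :meth:`EssentialityModel.fit` returns an
:class:`EssentialityResults` carrying phi estimates, per-gene
log-likelihood-ratio statistics T = ln L(phi_hat) - ln L(phi=0), and
empirical p-values against the negative-control null;
:meth:`EssentialityResults.differential` performs the differential
essentiality LRT between test and control sample panels
(T' = ln [L(phi_t) L(phi_c) / L(phi_shared)]).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, xlogy

from .data import ScreenDataset, GuideLibrary
from .features import EPSILON_CLAMP, gc_decile_features, guide_efficiency
from .likelihood import LikelihoodGrid, LikelihoodOptions, _logsumexp_last
from .normalization import estimate_master_fractions, estimate_scaling_factors

OMEGA_INIT = 8.0  # expit(8) ~ 0.99966: start with all guides ~100% effective
OMEGA_BOUNDS = (-15.0, 15.0)


@dataclass
class FitConfig:
    """Optimizer settings for the coordinate-ascent fit."""

    phi_bounds: tuple[float, float] = (-5.0, 1.0)
    brent_tol: float = 1e-4
    max_outer_iters: int = 50
    convergence_tol: float = 1e-3
    seed: int | None = None
    parallel_genes: bool = False  # accepted for interface parity; fit is vectorized

    def __post_init__(self) -> None:
        if self.phi_bounds[1] != 1.0:
            raise ValueError("upper phi bound must be 1 (survivor mean nonnegativity)")
        if self.brent_tol <= 0 or self.convergence_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ModelState:
    """Fitted parameters: per-gene phi, efficiency weights and scalings."""

    phi: pd.Series
    omega: np.ndarray
    feature_bins: np.ndarray
    gamma_initial: np.ndarray | None
    gamma_final: np.ndarray

    @property
    def epsilon(self) -> np.ndarray:
        """Per-guide efficiency, always recomputed from omega (logistic)."""
        eps_bin = np.clip(expit(self.omega), EPSILON_CLAMP, 1 - EPSILON_CLAMP)
        return eps_bin[self.feature_bins]

    @property
    def epsilon_by_bin(self) -> np.ndarray:
        return np.clip(expit(self.omega), EPSILON_CLAMP, 1 - EPSILON_CLAMP)


def empirical_pvalues(statistics, null_statistics, smoothing: str = "add_one") -> np.ndarray:
    """Empirical p-values of test statistics against a null sample.

    ``smoothing='add_one'`` gives p = (1 + #{null >= T}) / (1 + N), the
    permutation-test convention that never returns 0; ``'plugin'`` gives
    p = #{null >= T} / N, which can reach 0 and is what a fixed
    "exceeds every null value" detection threshold corresponds to.
    Ties count against significance (null values equal to T are >= T).
    """
    T = np.asarray(statistics, dtype=float)
    null = np.sort(np.asarray(null_statistics, dtype=float))
    N = null.size
    if N == 0:
        raise ValueError("empty null statistic set")
    if N < 20:
        warnings.warn(f"only {N} null statistics; empirical p-values are coarse", stacklevel=2)
    k = N - np.searchsorted(null, T, side="left")
    if smoothing == "add_one":
        return (1.0 + k) / (1.0 + N)
    if smoothing == "plugin":
        return k / N
    raise ValueError("smoothing must be 'add_one' or 'plugin'")


def adjust_pvalues(p, method: str = "bonferroni", n_tests: int | None = None) -> np.ndarray:
    """Multiple-testing adjustment; only Bonferroni is needed here."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if method != "bonferroni":
        raise ValueError("unsupported adjustment method")
    n = p.size if n_tests is None else n_tests
    return np.minimum(1.0, p * n)


class EssentialityModel:
    """Hierarchical Poisson model of a CRISPR negative-selection screen.

    Parameters
    ----------
    dataset : ScreenDataset
    library : GuideLibrary
        Must cover every guide in the dataset (checked here).
    negative_controls : collection of gene ids, optional
        Used for scaling-factor estimation (default reference) and for
        the empirical null distributions of the LRT statistics.
    options : LikelihoodOptions, optional
        Defaults to bundled summation (width 10) with a 12-sigma latent
        window; the master/initial flags are aligned with what the
        dataset actually contains.
    reference : 'negative_controls', 'all', or explicit gene collection
        Reference set for median-of-ratios normalization.
    prior : 'auto' or 'uniform'
        'auto' uses Pois(n | c*m) with m taken from the dataset or
        estimated from initial counts; 'uniform' forces the uniform
        prior over {0..c} (the no-master-library design).
    """

    def __init__(
        self,
        dataset: ScreenDataset,
        library: GuideLibrary,
        *,
        negative_controls=None,
        options: LikelihoodOptions | None = None,
        reference=None,
        prior: str = "auto",
        n_efficiency_bins: int = 10,
    ):
        lib = library.reindex(dataset.guide_ids)
        order = np.argsort(dataset.gene_of_guide.astype(str), kind="stable")
        self.dataset = dataset
        self.guide_order = order
        self.guide_ids = dataset.guide_ids[order]
        self.gene_of_guide = dataset.gene_of_guide[order]
        self.gc = lib.gc_fraction[order]
        self.y = dataset.y_counts[:, order]
        self.x = None if dataset.x_counts is None else dataset.x_counts[:, order]

        _, starts = np.unique(self.gene_of_guide.astype(str), return_index=True)
        # np.unique sorts, and guides were sorted the same way: starts are slice origins
        self._starts = np.sort(starts)
        self.genes = self.gene_of_guide[self._starts]
        self._ends = np.append(self._starts[1:], len(self.guide_ids))
        self.gene_index_of_guide = np.searchsorted(self._starts, np.arange(len(self.guide_ids)), side="right") - 1

        self.negative_controls = None if negative_controls is None else set(negative_controls)

        if prior not in ("auto", "uniform"):
            raise ValueError("prior must be 'auto' or 'uniform'")
        m = dataset.master_fractions
        if m is None:
            if dataset.x_counts is None:
                raise ValueError(
                    "no master fractions and no initial counts: the infected-cell "
                    "scale cannot be anchored"
                )
            m = estimate_master_fractions(dataset.x_counts)
        self.master_fractions = np.asarray(m, dtype=float)[order]
        has_master = prior == "auto"

        if reference is None:
            reference = "negative_controls" if self.negative_controls else "all"
        gamma, gamma_final = estimate_scaling_factors(
            dataset,
            reference_genes=reference,
            negative_controls=self.negative_controls,
            master_fractions=m,
        )
        self.gamma = gamma
        self.gamma_final = gamma_final

        if options is None:
            options = LikelihoodOptions(window_sigma=12.0)
        self.options = LikelihoodOptions(
            summation_mode=options.summation_mode,
            bundle_width=options.bundle_width,
            has_master=has_master,
            has_initial_counts=options.has_initial_counts and self.x is not None,
            cell_count_cap=options.cell_count_cap,
            window_sigma=options.window_sigma,
        )

        self.features, self.feature_bins = gc_decile_features(self.gc, n_efficiency_bins)
        self.n_bins = n_efficiency_bins

        self.grid = LikelihoodGrid(
            y=self.y,
            x=self.x if self.options.has_initial_counts else None,
            m=self.master_fractions if self.options.has_master else None,
            cells=dataset.cells_infected,
            gamma=self.gamma,
            gamma_final=self.gamma_final,
            options=self.options,
        )

    # -- likelihood plumbing -------------------------------------------------

    def _r_vector(self, phi_by_gene: np.ndarray, eps_by_guide: np.ndarray) -> np.ndarray:
        return 1.0 - eps_by_guide * phi_by_gene[self.gene_index_of_guide]

    def per_gene_loglik(self, phi_by_gene, eps_by_guide, sample_idx=None) -> np.ndarray:
        per_pair = self.grid.per_pair_loglik(
            self._r_vector(np.asarray(phi_by_gene, float), eps_by_guide), sample_idx
        )
        per_guide = per_pair.sum(axis=0)
        return np.add.reduceat(per_guide, self._starts)

    def _gene_objective(self, gi: int, eps_slice: np.ndarray, sample_idx):
        sl = slice(self._starts[gi], self._ends[gi])

        def nll(phi: float) -> float:
            r = 1.0 - eps_slice * phi
            return -self.grid.total_loglik(r, sample_idx, sl)

        return nll

    @staticmethod
    def _maximize_scalar(nll, bounds, xatol, extra_candidates=()):
        res = minimize_scalar(nll, bounds=bounds, method="bounded", options={"xatol": xatol})
        best_x, best_f = float(res.x), float(res.fun)
        for c in extra_candidates:
            c = float(c)
            if bounds[0] <= c <= bounds[1]:
                f = float(nll(c))
                if f < best_f:
                    best_x, best_f = c, f
        return best_x, best_f

    # -- fitting ---------------------------------------------------------------

    def fit(self, config: FitConfig | None = None) -> "EssentialityResults":
        config = config or FitConfig()
        nb = self.n_bins
        omega = np.full(nb, OMEGA_INIT)
        phi = np.zeros(len(self.genes))
        bins_present = [b for b in range(nb) if np.any(self.feature_bins == b)]
        bin_guides = {b: np.flatnonzero(self.feature_bins == b) for b in bins_present}
        # gather each decile's subgrid once; the omega objective is then a
        # plain vectorized evaluation instead of a fancy-index per call
        bin_sub = {
            b: (
                self.grid.n_mid[:, idx],
                self.grid.base[:, idx],
                self.grid.y[:, idx],
            )
            for b, idx in bin_guides.items()
        }
        gp = self.gamma_final[:, None, None]

        def bin_nll(b: int, e: float, phi_b: np.ndarray) -> float:
            nm, base, yb = bin_sub[b]
            mu = gp * nm * (1.0 - e * phi_b)[None, :, None]
            ll = base + xlogy(yb[:, :, None], mu) - mu
            return -float(_logsumexp_last(ll).sum())

        def eps_from(om):
            return np.clip(expit(om), EPSILON_CLAMP, 1 - EPSILON_CLAMP)[self.feature_bins]

        loglik_path = [float(self.per_gene_loglik(phi, eps_from(omega)).sum())]
        converged = False
        n_iter = 0
        for n_iter in range(1, config.max_outer_iters + 1):
            phi_old, omega_old = phi.copy(), omega.copy()
            eps = eps_from(omega)
            for gi in range(len(self.genes)):
                sl = slice(self._starts[gi], self._ends[gi])
                nll = self._gene_objective(gi, eps[sl], None)
                phi[gi], _ = self._maximize_scalar(
                    nll, config.phi_bounds, config.brent_tol, (phi[gi], 0.0)
                )
            for b in bins_present:
                idx = bin_guides[b]
                phi_b = phi[self.gene_index_of_guide[idx]]

                def nll_omega(om: float, b=b, phi_b=phi_b) -> float:
                    e = float(np.clip(expit(om), EPSILON_CLAMP, 1 - EPSILON_CLAMP))
                    return bin_nll(b, e, phi_b)

                omega[b], _ = self._maximize_scalar(
                    nll_omega, OMEGA_BOUNDS, config.brent_tol, (omega[b],)
                )
            total = float(self.per_gene_loglik(phi, eps_from(omega)).sum())
            if total < loglik_path[-1] - 1e-6:
                raise RuntimeError(
                    f"coordinate ascent decreased the log-likelihood at iteration {n_iter}"
                )
            loglik_path.append(total)
            # omega is compared on the efficiency scale: near saturation the
            # logit coordinate moves freely while the model is unchanged
            d_eps = np.max(np.abs(expit(omega) - expit(omega_old)))
            delta = max(np.max(np.abs(phi - phi_old)), d_eps)
            if delta < config.convergence_tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"coordinate ascent did not converge in {config.max_outer_iters} outer "
                "iterations; returning the best state found",
                stacklevel=2,
            )

        # final gene pass against the final omega, so T >= 0 holds exactly
        eps = eps_from(omega)
        for gi in range(len(self.genes)):
            sl = slice(self._starts[gi], self._ends[gi])
            nll = self._gene_objective(gi, eps[sl], None)
            phi[gi], _ = self._maximize_scalar(
                nll, config.phi_bounds, config.brent_tol, (phi[gi], 0.0)
            )
        total = float(self.per_gene_loglik(phi, eps).sum())
        if total < loglik_path[-1] - 1e-6:
            raise RuntimeError("final gene pass decreased the log-likelihood")
        loglik_path.append(total)

        state = ModelState(
            phi=pd.Series(phi, index=self.genes, name="phi_hat"),
            omega=omega.copy(),
            feature_bins=self.feature_bins,
            gamma_initial=self.gamma,
            gamma_final=self.gamma_final,
        )
        return EssentialityResults(
            model=self,
            state=state,
            config=config,
            loglik_path=loglik_path,
            converged=converged,
            n_iter=n_iter,
        )


class EssentialityResults:
    """Results of the absolute-essentiality fit.

    ``gene_results`` holds, per gene: the ML estimate ``phi_hat``, the
    gene's maximized log-likelihood component, the component at phi = 0,
    the LRT statistic ``llr`` (T) and, when negative controls are known,
    empirical and Bonferroni-adjusted p-values.
    """

    def __init__(self, model, state, config, loglik_path, converged, n_iter):
        self.model = model
        self.state = state
        self.config = config
        self.loglik_path = list(loglik_path)
        self.converged = converged
        self.n_iter = n_iter

        eps = state.epsilon
        phi = state.phi.to_numpy()
        ll_full = model.per_gene_loglik(phi, eps)
        ll_null = model.per_gene_loglik(np.zeros_like(phi), eps)
        llr = ll_full - ll_null
        if np.any(llr < -10 * config.brent_tol):
            raise RuntimeError("negative absolute LRT beyond optimizer tolerance")
        llr = np.maximum(llr, 0.0)
        self.gene_results = pd.DataFrame(
            {
                "gene": model.genes,
                "n_guides": model._ends - model._starts,
                "phi_hat": phi,
                "loglik_full": ll_full,
                "loglik_null": ll_null,
                "llr": llr,
            }
        ).set_index("gene", drop=False)
        if model.negative_controls:
            self.attach_pvalues()

    @property
    def phi_hat(self) -> pd.Series:
        return self.state.phi

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1]

    def absolute_llr(self, gene) -> float:
        """T = ln L(phi_hat) - ln L(phi = 0) for one gene."""
        return float(self.gene_results.loc[gene, "llr"])

    def attach_pvalues(self, smoothing: str = "add_one") -> pd.DataFrame:
        nc = self.model.negative_controls
        if not nc:
            raise ValueError("no negative-control genes designated")
        null = self.gene_results.loc[self.gene_results["gene"].isin(nc), "llr"].to_numpy()
        p = empirical_pvalues(self.gene_results["llr"].to_numpy(), null, smoothing)
        self.gene_results["p_empirical"] = p
        self.gene_results["p_adjusted"] = adjust_pvalues(p, n_tests=len(p))
        return self.gene_results

    def differential(
        self,
        test: str | None = None,
        control: str | None = None,
        one_sided: bool = False,
        smoothing: str = "add_one",
        null_statistics=None,
    ) -> "DifferentialResults":
        """Likelihood-ratio test for differential essentiality.

        Sample panels come from the dataset's panel labels ('test' /
        'control') unless explicit labels are given.  Scaling factors and
        guide efficiencies stay fixed at the all-sample fit; only the
        essentiality parameters are re-estimated: a shared phi over both
        panels (null) against independent phi_test, phi_control
        (alternative).  ``one_sided`` zeroes T' unless
        phi_test > phi_control.  The empirical null is the designated
        negative controls' T' unless ``null_statistics`` is supplied
        (e.g. from :func:`simulated_null_statistics`).
        """
        model = self.model
        ds = model.dataset
        t_idx = ds.samples_in_panel(test or "test")
        c_idx = ds.samples_in_panel(control or "control")
        if t_idx.size == 0:
            raise ValueError(f"no samples in test panel {test or 'test'!r}")
        if c_idx.size == 0:
            raise ValueError(f"no samples in control panel {control or 'control'!r}")
        tc_idx = np.concatenate([t_idx, c_idx])

        eps = self.state.epsilon
        cfg = self.config
        n_genes = len(model.genes)
        phi_shared = np.empty(n_genes)
        phi_t = np.empty(n_genes)
        phi_c = np.empty(n_genes)
        llr = np.empty(n_genes)
        for gi in range(n_genes):
            sl = slice(model._starts[gi], model._ends[gi])
            e = eps[sl]
            nll_sh = model._gene_objective(gi, e, tc_idx)
            phi_shared[gi], f_sh = model._maximize_scalar(
                nll_sh, cfg.phi_bounds, cfg.brent_tol, (self.state.phi.iloc[gi], 0.0)
            )
            nll_t = model._gene_objective(gi, e, t_idx)
            phi_t[gi], f_t = model._maximize_scalar(
                nll_t, cfg.phi_bounds, cfg.brent_tol, (phi_shared[gi],)
            )
            nll_c = model._gene_objective(gi, e, c_idx)
            phi_c[gi], f_c = model._maximize_scalar(
                nll_c, cfg.phi_bounds, cfg.brent_tol, (phi_shared[gi],)
            )
            llr[gi] = f_sh - f_t - f_c  # ln L(phi_t) + ln L(phi_c) - ln L(shared)
        if np.any(llr < -10 * cfg.brent_tol):
            raise RuntimeError("negative differential LRT beyond optimizer tolerance")
        llr = np.maximum(llr, 0.0)
        if one_sided:
            llr = np.where(phi_t > phi_c, llr, 0.0)

        frame = pd.DataFrame(
            {
                "gene": model.genes,
                "phi_shared": phi_shared,
                "phi_test": phi_t,
                "phi_control": phi_c,
                "llr": llr,
            }
        ).set_index("gene", drop=False)
        if null_statistics is None and model.negative_controls:
            null_statistics = frame.loc[
                frame["gene"].isin(model.negative_controls), "llr"
            ].to_numpy()
        if null_statistics is not None:
            p = empirical_pvalues(frame["llr"].to_numpy(), null_statistics, smoothing)
            frame["p_empirical"] = p
            frame["p_adjusted"] = adjust_pvalues(p, n_tests=len(p))
        return DifferentialResults(self, frame, one_sided=one_sided, smoothing=smoothing)

    def summary(self, top: int = 10) -> str:
        gr = self.gene_results.sort_values("llr", ascending=False)
        lines = [
            "Gene essentiality fit (hierarchical Poisson, coordinate ascent)",
            "=" * 64,
            f"genes: {len(gr)}   guides: {len(self.model.guide_ids)}   "
            f"samples: {self.model.dataset.n_samples}",
            f"outer iterations: {self.n_iter}   converged: {self.converged}",
            f"log-likelihood: {self.loglik:.3f}",
            "per-decile efficiency: "
            + " ".join(f"{e:.3f}" for e in self.state.epsilon_by_bin),
            "",
            f"top {top} genes by essentiality LLR:",
        ]
        cols = [c for c in ("phi_hat", "llr", "p_empirical", "p_adjusted") if c in gr.columns]
        lines.append(gr[cols].head(top).to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class DifferentialResults:
    """Results of the differential-essentiality LRT."""

    def __init__(self, parent: EssentialityResults, frame: pd.DataFrame, one_sided, smoothing):
        self.parent = parent
        self.gene_results = frame
        self.one_sided = one_sided
        self.smoothing = smoothing

    def detected(self, alpha: float = 0.05) -> pd.Series:
        if "p_adjusted" not in self.gene_results:
            raise ValueError("no p-values attached (no null statistics available)")
        return self.gene_results["p_adjusted"] < alpha

    def summary(self, top: int = 10) -> str:
        gr = self.gene_results.sort_values("llr", ascending=False)
        lines = [
            "Differential essentiality test (test vs control panels)",
            "=" * 60,
            f"genes tested: {len(gr)}   one-sided: {self.one_sided}",
            f"top {top} genes by differential LLR:",
        ]
        cols = [
            c
            for c in ("phi_test", "phi_control", "llr", "p_empirical", "p_adjusted")
            if c in gr.columns
        ]
        lines.append(gr[cols].head(top).to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def simulated_null_statistics(
    results: EssentialityResults,
    n_genes: int = 300,
    guides_per_gene: int = 4,
    seed: int = 0,
    sigma_m: float | None = None,
    sigma_x: float | None = None,
    sigma_y: float | None = None,
) -> np.ndarray:
    """Differential-LRT null statistics from simulated nonessential genes.

    Simulates ``n_genes`` label-preserving nonessential genes with the
    screen's own layout (read depths, cell counts, panel labels), fits
    phi per panel with the parent fit's scaling factors, and returns the
    T' values.  Dispersion parameters default to moderate screen noise
    (20% infection CV, 10% sequencing CV at the mean guide abundance).
    """
    from .simulate import SimSpec, simulate_screen

    model = results.model
    ds = model.dataset
    rng = np.random.default_rng(seed)
    n_guides = n_genes * guides_per_gene
    m = rng.choice(model.master_fractions, size=n_guides, replace=True)
    m = m / m.sum() * min(1.0, model.master_fractions.sum())
    mbar = m.mean()
    spec = SimSpec(
        master_fractions=m,
        gene_index=np.repeat(np.arange(n_genes), guides_per_gene),
        phi_by_gene=np.zeros(n_genes),
        epsilon_by_guide=np.ones(n_guides),
        sigma_m=sigma_m if sigma_m is not None else mbar / 0.2**2,
        sigma_x=sigma_x if sigma_x is not None else mbar / 0.1**2,
        sigma_y=sigma_y if sigma_y is not None else mbar / 0.1**2,
        depth_initial=(
            np.ones(ds.n_samples) if ds.x_counts is None else ds.x_counts.sum(axis=1) * m.sum()
        ),
        depth_final=ds.y_counts.sum(axis=1) * m.sum(),
        n_samples=ds.n_samples,
        seed=int(rng.integers(2**31 - 1)),
    )
    x_sim, y_sim, _ = simulate_screen(spec)
    grid = LikelihoodGrid(
        y=y_sim,
        x=None if ds.x_counts is None else x_sim,
        m=m,
        cells=ds.cells_infected,
        gamma=model.gamma,
        gamma_final=model.gamma_final,
        options=model.options,
    )
    t_idx = ds.samples_in_panel("test")
    c_idx = ds.samples_in_panel("control")
    tc_idx = np.concatenate([t_idx, c_idx])
    cfg = results.config
    out = np.empty(n_genes)
    for gi in range(n_genes):
        sl = slice(gi * guides_per_gene, (gi + 1) * guides_per_gene)

        def make_nll(idx):
            def nll(phi):
                return -grid.total_loglik(np.full(guides_per_gene, 1.0 - phi), idx, sl)

            return nll

        ph_sh, f_sh = EssentialityModel._maximize_scalar(
            make_nll(tc_idx), cfg.phi_bounds, cfg.brent_tol, (0.0,)
        )
        _, f_t = EssentialityModel._maximize_scalar(
            make_nll(t_idx), cfg.phi_bounds, cfg.brent_tol, (ph_sh,)
        )
        _, f_c = EssentialityModel._maximize_scalar(
            make_nll(c_idx), cfg.phi_bounds, cfg.brent_tol, (ph_sh,)
        )
        out[gi] = max(0.0, f_sh - f_t - f_c)
    return out
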