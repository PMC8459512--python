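"""Empirical-gamma simulator for CRISPR knockout screen counts.

The simulator mimics a template screen's noise with a chain of gamma
draws per guide g and sample s, independent of the inference model:

    mu_sg ~ Gamma(shape = sigma_m / m_g,          scale = m_g**2 / sigma_m)
    x_sg  = round(X_s * Gamma(shape = sigma_x / mu_sg, scale = mu_sg**2 / sigma_x))
    y_sg  = round(Y_s * Gamma(shape = sigma_y / d_sg,  scale = d_sg**2  / sigma_y))

with d_sg = (1 - eps_g * phi) * mu_sg, X_s / Y_s the per-sample target
read totals and m_g the master-library fraction of the guide.  Under the
shape-scale parameterization every stage has the intended mean (E[mu] =
m_g, E[x] = X_s * m_g, ...); the dispersions sigma_m (infection),
sigma_x and sigma_y (sequencing) set the squared coefficient of
variation of each stage to m / sigma (so larger sigma = less noise).
Each replicate is a separate infection, so mu_sg is drawn independently
per guide *and* sample, and x and y of the same sample share the draw.

No code in this module evaluates the inference likelihood; the
benchmark layouts built here are the shared ground truth for both the
hierarchical-Poisson fit and the fold-change baseline.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GuideLibrary, ScreenDataset

# Benchmark study conditions (per-guide means; see docs/methods.md).
# The benchmark library is balanced (equal master fractions, matching the
# "~300 reads per guide" design); cells per guide are set so the Poisson
# prior's relative width (1/sqrt(100) = 10%) is commensurate with the
# simulated infection noise, the regime in which the latent-cell
# integration accounts for the overdispersion it is meant to absorb.
READS_PER_GUIDE = 300.0
COVERAGE_CELLS_PER_GUIDE = 100.0
CV_INFECTION = 0.20
CV_SEQUENCING = 0.10
BENCHMARK_MASTER_SDLOG = 0.0
MASTER_SDLOG = 0.5
GUIDES_PER_GENE = 4
REPLICATES = 3


@dataclass
class SimSpec:
    """Configuration of one simulated screen.

    ``phi_by_gene`` is either a (n_genes,) vector (same essentiality in
    every sample) or a (n_samples, n_genes) matrix for differential
    designs.  ``depth_initial``/``depth_final`` are per-sample target
    read totals (scalar = same for all samples).
    """

    master_fractions: np.ndarray
    gene_index: np.ndarray
    phi_by_gene: np.ndarray
    epsilon_by_guide: np.ndarray
    sigma_m: float
    sigma_x: float
    sigma_y: float
    depth_initial: float | np.ndarray
    depth_final: float | np.ndarray
    n_samples: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.master_fractions = np.asarray(self.master_fractions, dtype=float)
        self.gene_index = np.asarray(self.gene_index, dtype=int)
        self.phi_by_gene = np.asarray(self.phi_by_gene, dtype=float)
        self.epsilon_by_guide = np.asarray(self.epsilon_by_guide, dtype=float)
        if np.any(self.master_fractions < 0):
            raise ValueError("master fractions must be nonnegative")
        if min(self.sigma_m, self.sigma_x, self.sigma_y) <= 0:
            raise ValueError("dispersions must be positive")
        self.depth_initial = np.broadcast_to(
            np.asarray(self.depth_initial, dtype=float), (self.n_samples,)
        ).copy()
        self.depth_final = np.broadcast_to(
            np.asarray(self.depth_final, dtype=float), (self.n_samples,)
        ).copy()
        if np.any(self.depth_initial <= 0) or np.any(self.depth_final <= 0):
            raise ValueError("target depths must be positive")
        if np.any((self.epsilon_by_guide < 0) | (self.epsilon_by_guide > 1)):
            raise ValueError("epsilon must lie in [0, 1]")
        if np.any(self.phi_by_gene > 1):
            raise ValueError("phi must be <= 1")
        if self.phi_by_gene.ndim == 1:
            self.phi_by_gene = np.broadcast_to(
                self.phi_by_gene, (self.n_samples, self.phi_by_gene.size)
            ).copy()
        elif self.phi_by_gene.shape[0] != self.n_samples:
            raise ValueError("phi_by_gene matrix must have one row per sample")

    @property
    def n_guides(self) -> int:
        return self.master_fractions.size


def _gamma_stage(rng: np.random.Generator, mean: np.ndarray, sigma: float) -> np.ndarray:
    """Gamma draw with the given mean and CV^2 = mean / sigma; 0 stays 0."""
    out = np.zeros_like(mean)
    pos = mean > 0
    out[pos] = rng.gamma(shape=sigma / mean[pos], scale=mean[pos] ** 2 / sigma)
    return out


def simulate_screen(spec: SimSpec):
    """Simulate one screen; returns ``(x_counts, y_counts, truth)``.

    ``truth`` is a dict with the per-guide-sample infection draws
    ``mu_hat`` and the phi / epsilon / m assignments.  Counts are
    half-to-even rounded and floored at zero; a guide with m_g = 0 gets
    zero counts with a warning; a guide-sample with (1 - eps*phi) *
    mu = 0 gets y = 0 deterministically.
    """
    rng = np.random.default_rng(spec.seed)
    S, G = spec.n_samples, spec.n_guides
    m = spec.master_fractions
    if np.any(m == 0):
        warnings.warn("guides with zero master fraction produce zero counts", stacklevel=2)
    x = np.zeros((S, G), dtype=np.int64)
    y = np.zeros((S, G), dtype=np.int64)
    mu_hat = np.zeros((S, G))
    for s in range(S):
        mu = _gamma_stage(rng, m, spec.sigma_m)
        mu_hat[s] = mu
        x[s] = np.maximum(0, np.rint(spec.depth_initial[s] * _gamma_stage(rng, mu, spec.sigma_x)))
        r = 1.0 - spec.epsilon_by_guide * spec.phi_by_gene[s, spec.gene_index]
        d = r * mu
        y[s] = np.maximum(0, np.rint(spec.depth_final[s] * _gamma_stage(rng, d, spec.sigma_y)))
    truth = {
        "mu_hat": mu_hat,
        "phi_by_gene": spec.phi_by_gene.copy(),
        "epsilon_by_guide": spec.epsilon_by_guide.copy(),
        "master_fractions": m.copy(),
        "gene_index": spec.gene_index.copy(),
    }
    return x, y, truth


def sample_master(template_master_counts, n_guides: int, seed: int = 0,
                  replace: bool = True) -> np.ndarray:
    """Master fractions drawn from a template library's read fractions.

    Samples ``n_guides`` fractions (with replacement by default) from
    the template's empirical distribution and renormalizes to sum to 1.
    """
    counts = np.asarray(template_master_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty template master library")
    if not replace and counts.size < n_guides:
        raise ValueError("template smaller than requested library; use replace=True")
    fractions = counts / counts.sum()
    rng = np.random.default_rng(seed)
    draw = rng.choice(fractions, size=n_guides, replace=replace)
    return draw / draw.sum()


def synthetic_master_fractions(n_guides: int, seed: int = 0,
                               sdlog: float = MASTER_SDLOG) -> np.ndarray:
    """Synthetic stand-in master library: lognormal abundance spread.

    Used when no template screen is supplied; sdlog = 0.5 emulates a
    well-constructed library (~1.4x quartile spread), far tighter than
    degraded libraries whose fractions span orders of magnitude.
    """
    rng = np.random.default_rng(seed)
    m = rng.lognormal(mean=0.0, sigma=sdlog, size=n_guides)
    return m / m.sum()


# -- template dispersion fitting ---------------------------------------------


def screen_summary_stats(x_counts, y_counts) -> np.ndarray:
    """Five noise summary statistics of a replicated screen.

    A documented stand-in set: median per-guide across-replicate CV of
    (1) initial and (2) final counts; (3) median per-guide
    across-replicate variance of log((y+0.5)/(x+0.5)) (infection noise
    cancels, isolating sequencing noise); median between-replicate
    correlation of (4) log initial and (5) log final counts (library
    spread relative to total noise).
    """
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 replicates to estimate dispersions")
    xf = x / x.sum(axis=1, keepdims=True)
    yf = y / y.sum(axis=1, keepdims=True)

    def med_cv(f):
        mu = f.mean(axis=0)
        sd = f.std(axis=0, ddof=1)
        ok = mu > 0
        return float(np.median(sd[ok] / mu[ok]))

    lr = np.log((y + 0.5) / (x + 0.5))
    lr = lr - lr.mean(axis=1, keepdims=True)
    s3 = float(np.median(lr.var(axis=0, ddof=1)))

    def med_cor(mat):
        lm = np.log(mat + 0.5)
        R = mat.shape[0]
        cors = [
            np.corrcoef(lm[i], lm[j])[0, 1] for i in range(R) for j in range(i + 1, R)
        ]
        return float(np.median(cors))

    return np.array([med_cv(xf), med_cv(yf), s3, med_cor(x), med_cor(y)])


def dispersion_objective(
    log_sigmas, template_stats, m, depth_initial, depth_final, n_samples, seed
) -> float:
    """Relative squared error between simulated and template summary stats."""
    sm, sx, sy = np.exp(np.asarray(log_sigmas, dtype=float))
    n_genes = m.size
    spec = SimSpec(
        master_fractions=m,
        gene_index=np.arange(n_genes),
        phi_by_gene=np.zeros(n_genes),
        epsilon_by_guide=np.ones(n_genes),
        sigma_m=sm,
        sigma_x=sx,
        sigma_y=sy,
        depth_initial=depth_initial,
        depth_final=depth_final,
        n_samples=n_samples,
        seed=seed,
    )
    x, y, _ = simulate_screen(spec)
    stats = screen_summary_stats(x, y)
    denom = np.maximum(np.abs(template_stats), 1e-3)
    return float(np.sum(((stats - template_stats) / denom) ** 2))


def fit_template_dispersions(template_x, template_y, template_master=None, seed: int = 0):
    """Estimate ``(sigma_m, sigma_x, sigma_y)`` from a replicated template.

    Matches five summary statistics of simulated data to the template's
    (unweighted relative squared error), seeding a Nelder-Mead search
    with closed-form moment estimates: writing a = var log x, b = var
    log y across replicates and c = var log(y/x), the per-stage CVs are
    cv_x^2 = (a + c - b)/2, cv_y^2 = (b + c - a)/2, cv_m^2 = a - cv_x^2,
    and sigma = m_mean / cv^2.
    """
    from scipy.optimize import minimize

    x = np.asarray(template_x, dtype=float)
    y = np.asarray(template_y, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("dispersion fitting needs >= 2 template replicates")
    if template_master is not None:
        m = np.asarray(template_master, dtype=float)
        m = m / m.sum()
    else:
        m = (x / x.sum(axis=1, keepdims=True)).mean(axis=0)
    stats = screen_summary_stats(x, y)

    xf = x / x.sum(axis=1, keepdims=True)
    yf = y / y.sum(axis=1, keepdims=True)
    a = float(np.median(np.log(xf + 1e-12).var(axis=0, ddof=1)))
    b = float(np.median(np.log(yf + 1e-12).var(axis=0, ddof=1)))
    lr = np.log((y + 0.5) / (x + 0.5))
    c = float(np.median((lr - lr.mean(axis=1, keepdims=True)).var(axis=0, ddof=1)))
    floor = 1e-4
    cvx2 = max((a + c - b) / 2, floor)
    cvy2 = max((b + c - a) / 2, floor)
    cvm2 = max(a - cvx2, floor)
    mbar = float(m.mean())
    init = np.log([mbar / cvm2, mbar / cvx2, mbar / cvy2])

    res = minimize(
        dispersion_objective,
        init,
        args=(stats, m, x.sum(axis=1).mean(), y.sum(axis=1).mean(), x.shape[0], seed),
        method="Nelder-Mead",
        options={"maxiter": 120, "xatol": 0.05, "fatol": 1e-4},
    )
    best = res.x if res.fun <= dispersion_objective(
        init, stats, m, x.sum(axis=1).mean(), y.sum(axis=1).mean(), x.shape[0], seed
    ) else init
    sm, sx, sy = np.exp(best)
    return float(sm), float(sx), float(sy)


# -- benchmark layouts ---------------------------------------------------------


def true_efficiency(gc: np.ndarray) -> np.ndarray:
    """Ground-truth guide efficiency as a smooth function of GC content.

    Peaks at 0.98 for mid-GC guides and falls to 0.75 at the extremes
    (mean ~0.90), reflecting the empirical GC dependence of editing.
    """
    return 0.98 - 0.92 * (np.asarray(gc, dtype=float) - 0.5) ** 2


def build_benchmark(
    design: str,
    level_values=None,
    seed: int = 0,
    scale: float = 1.0,
    guides_per_gene: int = GUIDES_PER_GENE,
    replicates: int = REPLICATES,
    reads_per_guide: float = READS_PER_GUIDE,
    coverage: float = COVERAGE_CELLS_PER_GUIDE,
    cv_infection: float = CV_INFECTION,
    cv_sequencing: float = CV_SEQUENCING,
    master_sdlog: float = BENCHMARK_MASTER_SDLOG,
    template_master_counts=None,
    n_negative_controls: int = 300,
):
    """Simulated benchmark screens for absolute or differential designs.

    ``design='absolute'``: 3150*scale nonessential genes plus, per level,
    300*scale genes (600*scale at level 0.99), three replicate samples.
    ``design='differential'``: one level (the first of ``level_values``):
    300*scale genes essential only in the test panel, 300*scale shared
    at 0.99 and at 0.5, and 3150*scale shared nonessential genes;
    ``replicates`` samples per panel.  In both designs
    ``n_negative_controls`` nonessential genes (300, deliberately not
    scaled) are the designated negative controls.

    Returns ``(dataset, library, truth, negative_controls)``.  The
    dataset carries only initial/final counts (master fractions stay in
    the truth table: the fitted model estimates them from the initial
    counts, as the benchmarked methods see no master library).
    """
    if design not in ("absolute", "differential"):
        raise ValueError("design must be 'absolute' or 'differential'")
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    if level_values is None:
        level_values = (0.1, 0.25, 0.5, 0.75, 0.9, 0.99) if design == "absolute" else (0.2,)
    level_values = [float(v) for v in level_values]
    if any(v > 1 for v in level_values):
        raise ValueError("essentiality levels must be <= 1")
    rng = np.random.default_rng(seed)

    def n_of(base: int) -> int:
        return max(1, int(round(base * scale)))

    classes: list[tuple[str, int, float, float]] = []  # (label, n, phi_test, phi_control)
    if design == "absolute":
        classes.append(("null", n_of(3150), 0.0, 0.0))
        for v in level_values:
            classes.append((f"phi_{v:g}", n_of(600 if v == 0.99 else 300), v, v))
    else:
        v = level_values[0]
        classes.append(("null", n_of(3150), 0.0, 0.0))
        classes.append(("uniform_0.99", n_of(300), 0.99, 0.99))
        classes.append(("uniform_0.5", n_of(300), 0.5, 0.5))
        classes.append((f"differential_{v:g}", n_of(300), v, 0.0))

    gene_ids, gene_class = [], []
    phi_test, phi_control = [], []
    for label, n, pt, pc in classes:
        for i in range(n):
            gene_ids.append(f"{label}_g{i:05d}")
            gene_class.append(label)
            phi_test.append(pt)
            phi_control.append(pc)
    n_genes = len(gene_ids)
    n_guides = n_genes * guides_per_gene
    gene_index = np.repeat(np.arange(n_genes), guides_per_gene)

    gc = rng.uniform(0, 1, size=n_guides)
    eps = true_efficiency(gc)
    if template_master_counts is not None:
        m = sample_master(template_master_counts, n_guides, seed=int(rng.integers(2**31 - 1)))
    else:
        m = synthetic_master_fractions(n_guides, seed=int(rng.integers(2**31 - 1)), sdlog=master_sdlog)
    mbar = float(m.mean())

    n_samples = replicates if design == "absolute" else 2 * replicates
    panel = (
        ["none"] * n_samples
        if design == "absolute"
        else ["test"] * replicates + ["control"] * replicates
    )
    phi_t = np.asarray(phi_test)
    phi_c = np.asarray(phi_control)
    phi_matrix = np.vstack(
        [phi_t if p in ("none", "test") else phi_c for p in panel]
    )

    depth = reads_per_guide * n_guides
    spec = SimSpec(
        master_fractions=m,
        gene_index=gene_index,
        phi_by_gene=phi_matrix,
        epsilon_by_guide=eps,
        sigma_m=mbar / cv_infection**2,
        sigma_x=mbar / cv_sequencing**2,
        sigma_y=mbar / cv_sequencing**2,
        depth_initial=depth,
        depth_final=depth,
        n_samples=n_samples,
        seed=int(rng.integers(2**31 - 1)),
    )
    x, y, sim_truth = simulate_screen(spec)

    guide_ids = np.array(
        [f"{gene_ids[gene_index[i]]}_sg{i % guides_per_gene}" for i in range(n_guides)],
        dtype=object,
    )
    gene_of_guide = np.array([gene_ids[j] for j in gene_index], dtype=object)
    dataset = ScreenDataset(
        guide_ids=guide_ids,
        gene_of_guide=gene_of_guide,
        x_counts=x,
        y_counts=y,
        cells_infected=np.full(n_samples, round(coverage * n_guides)),
        sample_ids=np.array(
            [f"{p}_{i}" for i, p in enumerate(panel)], dtype=object
        ),
        panel_labels=np.array(panel, dtype=object),
    )
    library = GuideLibrary(guide_ids=guide_ids, gene_of_guide=gene_of_guide, gc_fraction=gc)
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "gene_class": gene_class,
            "phi_test": phi_t,
            "phi_control": phi_c,
        }
    ).set_index("gene", drop=False)
    truth.attrs["sim"] = sim_truth

    # The designated control count is NOT scaled: it sets the empirical
    # p-value resolution (hence the Bonferroni detection threshold), so a
    # scaled-down run must keep the full design's 300 controls to measure
    # the same detection quantity.
    null_genes = [g for g, c in zip(gene_ids, gene_class) if c == "null"]
    negative_controls = null_genes[: min(n_negative_controls, len(null_genes))]
    return dataset, library, truth, negative_controls
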