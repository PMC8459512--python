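"""Simulation benchmarks: parameter recovery, classification and power.

Reproduces the simulation experiments at a configurable scale: generate
screens with the empirical-gamma simulator, fit the hierarchical
Poisson model and the AFC baseline, and summarize per essentiality
level the estimation error, the essential-vs-nonessential ROC AUC, and
(for differential designs) the fraction of truly differential genes
detected at a Bonferroni-corrected empirical p < 0.05.

The ``scale`` parameter shrinks every gene-class count proportionally
(the full 5250-gene layout is a multi-hour single-CPU job; scale 0.3 is
a desk-scale run with the same proportions).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .afc import afc_scores, afc_zscores
from .model import EssentialityModel, FitConfig, adjust_pvalues, empirical_pvalues
from .simulate import build_benchmark


def mann_whitney_auc(positive, negative) -> float:
    """ROC AUC via the rank-sum identity; ties get midranks."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one value in each class")
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    return float((rank_sum - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def _fit(dataset, library, negative_controls, fit_config, options):
    model = EssentialityModel(
        dataset, library, negative_controls=negative_controls, options=options
    )
    return model, model.fit(fit_config or FitConfig())


def run_absolute_benchmark(
    scale: float = 0.3,
    levels=(0.25, 0.5, 0.75, 0.99),
    seed: int = 0,
    fit_config: FitConfig | None = None,
    options=None,
    **design_kwargs,
):
    """Absolute-essentiality benchmark.

    Returns a dict with ``genes`` (per-gene table: true phi, phi_hat,
    LLR T, AFC, AFC z) and ``levels`` (per-level AUC of the LLR and of
    the AFC z-score against the nonessential genes, plus median
    estimates of both estimators).
    """
    if any(v > 1 for v in levels):
        raise ValueError("essentiality levels must be <= 1")
    dataset, library, truth, neg = build_benchmark(
        "absolute", level_values=levels, seed=seed, scale=scale, **design_kwargs
    )
    model, results = _fit(dataset, library, neg, fit_config, options)

    gr = results.gene_results
    afc = afc_scores(dataset.x_counts, dataset.y_counts, dataset.gene_of_guide, neg)
    afc_z = afc_zscores(afc, neg)
    genes = truth.join(gr[["phi_hat", "llr"]]).join(afc).join(afc_z)

    null_mask = genes["gene_class"] == "null"
    rows = []
    for v in levels:
        lv = genes["gene_class"] == f"phi_{v:g}"
        rows.append(
            {
                "level": v,
                "n_genes": int(lv.sum()),
                "auc_llr": mann_whitney_auc(genes.loc[lv, "llr"], genes.loc[null_mask, "llr"]),
                "auc_afc_z": mann_whitney_auc(
                    genes.loc[lv, "afc_z"], genes.loc[null_mask, "afc_z"]
                ),
                "median_phi_hat": float(genes.loc[lv, "phi_hat"].median()),
                "median_afc": float(genes.loc[lv, "afc"].median()),
            }
        )
    rows.append(
        {
            "level": 0.0,
            "n_genes": int(null_mask.sum()),
            "auc_llr": np.nan,
            "auc_afc_z": np.nan,
            "median_phi_hat": float(genes.loc[null_mask, "phi_hat"].median()),
            "median_afc": float(genes.loc[null_mask, "afc"].median()),
        }
    )
    return {
        "genes": genes,
        "levels": pd.DataFrame(rows).set_index("level"),
        "results": results,
        "seed": seed,
        "scale": scale,
    }


def run_differential_benchmark(
    scale: float = 0.3,
    levels=(0.2,),
    seed: int = 0,
    one_sided: bool = False,
    alpha: float = 0.05,
    fit_config: FitConfig | None = None,
    options=None,
    **design_kwargs,
):
    """Differential-essentiality benchmark (one simulated screen per level).

    Detection uses plug-in empirical p-values (p = #{null >= T'}/N over
    the designated negative-control genes, the convention under which a
    Bonferroni-corrected threshold is attainable with a finite null set)
    adjusted over all tested genes.  The AFC comparison statistic is the
    difference of per-panel AFC z-scores (a documented stand-in: the
    baseline has no native differential test).

    Returns a dict with ``levels`` (per-level detection fraction and
    AUCs) and ``runs`` (per-level per-gene tables).
    """
    if any(v > 1 for v in levels):
        raise ValueError("essentiality levels must be <= 1")
    rng = np.random.default_rng(seed)
    rows, runs = [], {}
    for v in levels:
        ds_seed = int(rng.integers(2**31 - 1))
        dataset, library, truth, neg = build_benchmark(
            "differential", level_values=[v], seed=ds_seed, scale=scale, **design_kwargs
        )
        model, results = _fit(dataset, library, neg, fit_config, options)
        diff = results.differential(one_sided=one_sided, smoothing="plugin")
        genes = truth.rename(
            columns={"phi_test": "phi_true_test", "phi_control": "phi_true_control"}
        ).join(diff.gene_results[["phi_test", "phi_control", "llr"]])
        genes["p_empirical"] = diff.gene_results["p_empirical"]
        genes["p_adjusted"] = diff.gene_results["p_adjusted"]

        t_idx = dataset.samples_in_panel("test")
        c_idx = dataset.samples_in_panel("control")
        z_panels = []
        for idx in (t_idx, c_idx):
            a = afc_scores(
                dataset.x_counts[idx], dataset.y_counts[idx], dataset.gene_of_guide, neg
            )
            z_panels.append(afc_zscores(a, neg))
        genes["afc_z_diff"] = z_panels[0] - z_panels[1]

        diff_mask = genes["gene_class"] == f"differential_{v:g}"
        nondiff_mask = ~diff_mask
        detected = genes.loc[diff_mask, "p_adjusted"] < alpha
        afc_stat = genes["afc_z_diff"].abs() if not one_sided else genes["afc_z_diff"]
        rows.append(
            {
                "level": v,
                "n_differential": int(diff_mask.sum()),
                "n_null": int(genes["gene_class"].eq("null").sum()),
                "detection_fraction": float(detected.mean()),
                "auc_llr": mann_whitney_auc(
                    genes.loc[diff_mask, "llr"], genes.loc[nondiff_mask, "llr"]
                ),
                "auc_afc": mann_whitney_auc(
                    afc_stat[diff_mask], afc_stat[nondiff_mask]
                ),
            }
        )
        runs[v] = genes
    return {
        "levels": pd.DataFrame(rows).set_index("level"),
        "runs": runs,
        "seed": seed,
        "scale": scale,
        "alpha": alpha,
    }
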