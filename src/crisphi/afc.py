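"""Average-fold-change (AFC) essentiality baseline.

The AFC score of a gene is one minus the geometric mean, over its guides
and all samples, of the depth-normalized final/initial read-count ratio,
re-centered so that the designated negative controls average exactly
zero:

    AFC_G = 1 - prod_{g in G, s} ( lambda'_s tau (0.5+y_sg) /
                                   (lambda_s (0.5+x_sg)) )^(1/(S*|G|))

with pseudocounts of 0.5 on both counts, per-sample normalizers
lambda_s = 1e7 / sum_g x_sg and lambda'_s = 1e7 / sum_g y_sg bringing
each sequencing run to ten million reads (when initial and final depths
are equal this collapses to a single common normalizer), and tau the
reciprocal geometric mean of the normalized ratios over the
negative-control guides.  AFC = 0 means no effect on growth; 1 means
complete depletion.  All geometric means are computed in log space.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

TOTAL_READS_NORM = 1e7


def afc_scores(x_counts, y_counts, gene_of_guide, negative_controls) -> pd.Series:
    """Per-gene AFC estimates of essentiality.

    ``negative_controls`` is a non-empty collection of gene ids whose
    guides define the zero point of the scale.
    """
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("x_counts and y_counts must be samples x guides of equal shape")
    genes = np.asarray(gene_of_guide, dtype=object)
    nc = set(negative_controls)
    if not nc:
        raise ValueError("empty negative-control set")
    mask_nc = np.array([g in nc for g in genes])
    if not mask_nc.any():
        raise ValueError("no negative-control guides found in the library")

    log_lam = np.log(TOTAL_READS_NORM) - np.log(x.sum(axis=1))
    log_lam_final = np.log(TOTAL_READS_NORM) - np.log(y.sum(axis=1))
    # log of lambda'_s (0.5+y) / (lambda_s (0.5+x)), per sample and guide
    lr = (
        log_lam_final[:, None]
        + np.log(0.5 + y)
        - log_lam[:, None]
        - np.log(0.5 + x)
    )
    log_tau = -lr[:, mask_nc].mean()
    per_gene = pd.Series(lr.mean(axis=0) + log_tau, index=genes).groupby(level=0).mean()
    afc = 1.0 - np.exp(per_gene)
    afc.name = "afc"
    afc.index.name = "gene"
    return afc


def afc_zscores(afc: pd.Series, negative_controls) -> pd.Series:
    """z-scores of AFC values against the negative-control distribution.

    Uses the sample standard deviation (ddof=1) of the controls' AFC.
    """
    nc = [g for g in afc.index if g in set(negative_controls)]
    if len(nc) < 2:
        raise ValueError("need >= 2 negative-control genes for z-scores")
    null = afc.loc[nc]
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("negative-control AFC standard deviation is zero")
    z = (afc - null.mean()) / sd
    z.name = "afc_z"
    return z
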