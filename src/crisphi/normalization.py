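"""Pre-processing estimation of sample scaling factors and master fractions.

The per-sample scaling factors gamma_s (initial sequencing) and
gamma'_s (final sequencing, which also absorbs global growth) are not
free parameters of the likelihood; they are fixed beforehand by a
median-of-ratios normalization against the expected infected-cell count
c_s * m_g of each reference guide, in the spirit of the size-factor
estimation used for differential-expression count models.  When no
master library was sequenced, the library fractions m_g are approximated
from the initial read counts averaged across samples.
"""
from __future__ import annotations

import warnings

import numpy as np


def estimate_master_fractions(x_counts) -> np.ndarray:
    """Per-guide master-library fractions from initial counts.

    ``m_g`` is the mean across samples of each guide's read fraction, so
    the result sums to 1.  A sample with zero total reads is an error.
    """
    x = np.asarray(x_counts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("x_counts must be a samples x guides matrix with >= 1 sample")
    totals = x.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(f"sample index {zero[0]} has zero total initial reads")
    return (x / totals[:, None]).mean(axis=0)


def _median_ratio(counts: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Per-sample median of counts / expected over the guide axis."""
    return np.median(counts / expected[None, :], axis=1)


def estimate_scaling_factors(
    dataset,
    reference_genes="negative_controls",
    negative_controls=None,
    master_fractions=None,
):
    """Median-of-ratios scaling factors ``(gamma, gamma_final)``.

    ``reference_genes`` selects the guides whose count/(c*m) ratios are
    medianed: ``"negative_controls"`` (default; requires
    ``negative_controls``, a collection of gene ids), ``"all"``, or an
    explicit collection of gene ids.  Guides with m_g = 0 are dropped
    with a warning; zero-count reference guides keep their (zero) ratio.
    Returns ``gamma=None`` when the dataset has no initial counts.
    """
    m = master_fractions
    if m is None:
        m = dataset.master_fractions
    if m is None:
        if dataset.x_counts is None:
            raise ValueError(
                "cannot estimate scaling factors: no master fractions and no initial counts"
            )
        m = estimate_master_fractions(dataset.x_counts)
    m = np.asarray(m, dtype=float)

    if isinstance(reference_genes, str) and reference_genes == "negative_controls":
        if negative_controls is None:
            raise ValueError("reference 'negative_controls' requires a negative-control gene set")
        ref_set = set(negative_controls)
        mask = np.array([g in ref_set for g in dataset.gene_of_guide])
    elif isinstance(reference_genes, str) and reference_genes == "all":
        mask = np.ones(dataset.n_guides, dtype=bool)
    else:
        ref_set = set(reference_genes)
        mask = np.array([g in ref_set for g in dataset.gene_of_guide])
    if not mask.any():
        raise ValueError("reference gene set is empty after intersecting with the library")

    zero_m = mask & (m <= 0)
    if zero_m.any():
        warnings.warn(
            f"{int(zero_m.sum())} reference guides with zero master fraction dropped "
            "from scaling-factor estimation",
            stacklevel=2,
        )
        mask = mask & (m > 0)
    if not mask.any():
        raise ValueError("all reference guides have zero master fraction")

    expected = dataset.cells_infected[:, None] * m[None, :]
    expected_ref = expected[:, mask]

    gamma = None
    if dataset.x_counts is not None:
        gamma = np.median(dataset.x_counts[:, mask] / expected_ref, axis=1)
        if np.any(gamma <= 0):
            warnings.warn(
                "a sample has zero median initial ratio (gamma = 0); "
                "the downstream fit will fail on its counts",
                stacklevel=2,
            )
    gamma_final = np.median(dataset.y_counts[:, mask] / expected_ref, axis=1)
    if np.any(gamma_final <= 0):
        warnings.warn(
            "a sample has zero median final ratio (gamma' = 0); "
            "the downstream fit will fail on its counts",
            stacklevel=2,
        )
    return gamma, gamma_final
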