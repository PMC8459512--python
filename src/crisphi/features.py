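"""Guide-efficiency features and the survivor-count map.

Guide efficiency eps_g is pooled across guides by logistic regression on
a one-hot feature vector; the default featurization bins guides into
empirical deciles of GC content, so one weight (hence one efficiency) is
learned per decile.  The deterministic growth map links the initial
number of infected cells n to the expected survivors d = n * (1 - eps*phi),
where phi <= 1 is the essentiality of the targeted gene.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit

#: Clamp for the logistic output: keeps eps strictly inside (0, 1) so the
#: final-count Poisson mean never collapses to exactly zero at phi = 1.
EPSILON_CLAMP = 1e-12


def gc_decile_features(gc_fractions, n_bins: int = 10):
    """One-hot decile features from per-guide GC fractions.

    Bin boundaries are empirical quantiles of the supplied values, so
    with continuous GC fractions each bin receives an equal share of
    guides.  Returns ``(features, bins)`` where ``features`` is a
    (n_guides, n_bins) 0/1 matrix with exactly one 1 per row and
    ``bins`` is the per-guide bin index (needed to map fitted weights
    back to per-decile efficiencies).
    """
    gc = np.asarray(gc_fractions, dtype=float)
    if gc.size == 0:
        raise ValueError("no GC fractions supplied")
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("GC fractions must lie in [0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.quantile(gc, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, gc, side="right")
    if np.unique(gc).size < n_bins:
        warnings.warn(
            "fewer distinct GC values than bins; some efficiency bins are empty",
            stacklevel=2,
        )
    features = np.zeros((gc.size, n_bins))
    features[np.arange(gc.size), bins] = 1.0
    return features, bins


def guide_efficiency(omega, features):
    """Logistic-regression guide efficiency eps = expit(omega . F).

    Accepts a single feature vector or a (n_guides, n_features) matrix.
    The output is clamped to the open interval (0, 1).
    """
    omega = np.asarray(omega, dtype=float)
    F = np.asarray(features, dtype=float)
    if F.shape[-1] != omega.shape[0]:
        raise ValueError(
            f"feature dimension {F.shape[-1]} does not match weight dimension {omega.shape[0]}"
        )
    eps = expit(F @ omega)
    return np.clip(eps, EPSILON_CLAMP, 1.0 - EPSILON_CLAMP)


def expected_survivors(n, epsilon, phi):
    """Expected surviving cells d = n * (1 - eps * phi).

    phi = 1 with eps = 1 drives d to zero (complete essentiality);
    phi = 0 leaves d = n; negative phi models a growth advantage.
    """
    n = np.asarray(n, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(n < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any((epsilon < 0) | (epsilon > 1)):
        raise ValueError("efficiency must lie in [0, 1]")
    if np.any(phi > 1):
        raise ValueError("essentiality phi > 1 would give a negative survivor mean")
    return n * (1.0 - epsilon * phi)
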