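"""Containers for guide-level CRISPR screen count data.

A pooled knockout screen counts sequencing reads per single-guide RNA
(sgRNA) in one or more samples, at up to two time points: just after
infection (``x``, the *initial* counts) and after the selection/growth
period (``y``, the *final* counts).  Optionally the plasmid/lentiviral
master library itself is sequenced, giving per-guide library fractions
``m_g``.  :class:`ScreenDataset` holds these observations together with
the per-sample infected-cell counts ``c_s`` and optional test/control
panel labels; :class:`GuideLibrary` maps guides to their target genes
and carries the GC fraction used to pool guide-efficiency information.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANEL_LABELS = ("test", "control", "none")

#: Default number of infected cells assumed per sample when the user
#: provides none.
DEFAULT_CELLS_PER_SAMPLE = 1000

_VALID_BASES = set("ACGT")


def gc_content(sequence: str) -> float:
    """GC fraction of a guide sequence, case-insensitive.

    Raises ``ValueError`` on empty sequences or characters outside ACGT.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty guide sequence")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-ACGT characters in guide sequence: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class GuideLibrary:
    """Guide-to-gene map with per-guide GC fraction."""

    guide_ids: np.ndarray
    gene_of_guide: np.ndarray
    gc_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.guide_ids = np.asarray(self.guide_ids, dtype=object)
        self.gene_of_guide = np.asarray(self.gene_of_guide, dtype=object)
        self.gc_fraction = np.asarray(self.gc_fraction, dtype=float)
        if not (len(self.guide_ids) == len(self.gene_of_guide) == len(self.gc_fraction)):
            raise ValueError("guide_ids, gene_of_guide and gc_fraction must be equally long")
        if len(np.unique(self.guide_ids)) != len(self.guide_ids):
            raise ValueError("duplicate guide ids in library")
        if np.any((self.gc_fraction < 0) | (self.gc_fraction > 1)):
            raise ValueError("gc_fraction outside [0, 1]")
        self._index = {g: i for i, g in enumerate(self.guide_ids)}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GuideLibrary":
        """Build from a table with columns ``guide``, ``gene`` and either
        ``sequence`` or ``gc_fraction``."""
        cols = {c.lower(): c for c in df.columns}
        if "guide" not in cols or "gene" not in cols:
            raise ValueError("library table needs 'guide' and 'gene' columns")
        if "gc_fraction" in cols:
            gc = df[cols["gc_fraction"]].astype(float).to_numpy()
        elif "sequence" in cols:
            gc = np.array([gc_content(s) for s in df[cols["sequence"]]])
        else:
            raise ValueError("library table needs a 'sequence' or 'gc_fraction' column")
        return cls(
            guide_ids=df[cols["guide"]].to_numpy(dtype=object),
            gene_of_guide=df[cols["gene"]].to_numpy(dtype=object),
            gc_fraction=gc,
        )

    def __len__(self) -> int:
        return len(self.guide_ids)

    def reindex(self, guide_ids: np.ndarray) -> "GuideLibrary":
        """Library restricted to and ordered by ``guide_ids``.

        Raises ``KeyError`` naming the first guide missing from the library.
        """
        idx = []
        for g in guide_ids:
            if g not in self._index:
                raise KeyError(f"guide {g!r} present in counts but absent from the library")
            idx.append(self._index[g])
        idx = np.asarray(idx, dtype=int)
        return GuideLibrary(self.guide_ids[idx], self.gene_of_guide[idx], self.gc_fraction[idx])


@dataclass
class ScreenDataset:
    """Observed data of one screen: count matrices plus per-sample metadata.

    ``x_counts`` and ``y_counts`` are samples x guides integer matrices;
    ``x_counts`` and ``master_fractions`` may be absent depending on the
    experimental design.  ``panel_labels`` marks each sample as 'test',
    'control' or 'none' for differential-essentiality analyses.
    """

    guide_ids: np.ndarray
    gene_of_guide: np.ndarray
    y_counts: np.ndarray
    x_counts: np.ndarray | None = None
    master_fractions: np.ndarray | None = None
    cells_infected: np.ndarray | None = None
    sample_ids: np.ndarray | None = None
    panel_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.guide_ids = np.asarray(self.guide_ids, dtype=object)
        self.gene_of_guide = np.asarray(self.gene_of_guide, dtype=object)
        self.y_counts = self._check_counts(np.asarray(self.y_counts), "y_counts")
        S, G = self.y_counts.shape
        if len(self.guide_ids) != G or len(self.gene_of_guide) != G:
            raise ValueError("guide annotations do not match the count matrix width")
        if len(np.unique(self.guide_ids)) != G:
            raise ValueError("duplicate guide ids")
        if self.x_counts is not None:
            self.x_counts = self._check_counts(np.asarray(self.x_counts), "x_counts")
            if self.x_counts.shape != (S, G):
                raise ValueError("x_counts and y_counts shapes differ")
        if self.master_fractions is not None:
            m = np.asarray(self.master_fractions, dtype=float)
            if m.shape != (G,):
                raise ValueError("master_fractions must have one entry per guide")
            if np.any(m < 0):
                raise ValueError("master_fractions must be nonnegative")
            if m.sum() > 1 + 1e-6:
                raise ValueError("master_fractions sum exceeds 1")
            self.master_fractions = m
        if self.cells_infected is None:
            self.cells_infected = np.full(S, DEFAULT_CELLS_PER_SAMPLE, dtype=float)
        else:
            c = np.asarray(self.cells_infected, dtype=float)
            if c.shape == ():
                c = np.full(S, float(c))
            if c.shape != (S,) or np.any(c < 1):
                raise ValueError("cells_infected must be >= 1 for every sample")
            self.cells_infected = c
        if self.sample_ids is None:
            self.sample_ids = np.array([f"sample_{i}" for i in range(S)], dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if len(self.sample_ids) != S:
                raise ValueError("sample_ids length mismatch")
        if self.panel_labels is None:
            self.panel_labels = np.full(S, "none", dtype=object)
        else:
            self.panel_labels = np.asarray(self.panel_labels, dtype=object)
            if len(self.panel_labels) != S:
                raise ValueError("panel_labels length mismatch")
            bad = set(self.panel_labels) - set(PANEL_LABELS)
            if bad:
                raise ValueError(f"unknown panel labels: {sorted(bad)}")

    @staticmethod
    def _check_counts(a: np.ndarray, name: str) -> np.ndarray:
        if a.ndim != 2:
            raise ValueError(f"{name} must be a samples x guides matrix")
        if not np.issubdtype(a.dtype, np.integer):
            if not np.allclose(a, np.round(a)):
                raise ValueError(f"{name} contains non-integer values")
            a = np.round(a).astype(np.int64)
        if np.any(a < 0):
            raise ValueError(f"{name} contains negative counts")
        return a.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return self.y_counts.shape[0]

    @property
    def n_guides(self) -> int:
        return self.y_counts.shape[1]

    @property
    def genes(self) -> np.ndarray:
        return pd.unique(pd.Series(self.gene_of_guide))

    def samples_in_panel(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.panel_labels == label)

    def guides_of_gene(self, gene) -> np.ndarray:
        idx = np.flatnonzero(self.gene_of_guide == gene)
        if idx.size == 0:
            raise KeyError(f"unknown gene {gene!r}")
        return idx
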