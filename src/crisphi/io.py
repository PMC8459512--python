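"""Reading and writing the TSV/YAML/JSON formats used by the tool.

Count matrices are tab-separated UTF-8 with Unix newlines: a header row
of sample ids, a first column of guide ids, integer cells.  The guide
library is a TSV with columns guide, gene and sequence or gc_fraction.
The sample sheet has columns sample_id and optionally cells_infected
(default 1000) and panel (test/control/none).  Every result file is
accompanied by run metadata carrying a hash of the configuration, so a
run can be audited and reproduced.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DEFAULT_CELLS_PER_SAMPLE, GuideLibrary, PANEL_LABELS


def read_counts(path):
    """Read a guide x sample count TSV; returns (counts, guide_ids, sample_ids).

    ``counts`` is a samples x guides integer matrix.  Duplicate guide
    ids, missing cells, non-integer or negative values are errors with
    row/column context.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated guide id {dup!r}")
    if df.isna().any().any():
        row, col = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at guide {df.index[row]!r}, sample {df.columns[col]!r}")
    try:
        mat = df.astype(np.int64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer count ({exc})") from None
    neg = np.argwhere(mat.to_numpy() < 0)
    if neg.size:
        row, col = neg[0]
        raise ValueError(
            f"{path}: negative count at guide {df.index[row]!r}, sample {df.columns[col]!r}"
        )
    return (
        mat.to_numpy().T.copy(),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def write_counts(path, counts, guide_ids, sample_ids) -> None:
    """Inverse of :func:`read_counts` (counts given as samples x guides)."""
    df = pd.DataFrame(
        np.asarray(counts).T, index=pd.Index(guide_ids, name="guide"), columns=sample_ids
    )
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_library(path) -> GuideLibrary:
    """Read a guide library TSV (guide, gene, sequence or gc_fraction)."""
    return GuideLibrary.from_dataframe(pd.read_csv(path, sep="\t", dtype=str))


def read_sample_sheet(path, sample_ids):
    """Per-sample cell counts and panel labels, aligned to ``sample_ids``.

    Returns ``(cells_infected, panel_labels)`` arrays.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ValueError(f"{path}: sample sheet needs a 'sample_id' column")
    df = df.set_index(cols["sample_id"])
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValueError(f"{path}: sample {missing[0]!r} absent from the sample sheet")
    df = df.loc[list(sample_ids)]
    if "cells_infected" in cols:
        cells = df[cols["cells_infected"]].astype(float).to_numpy()
    else:
        cells = np.full(len(sample_ids), float(DEFAULT_CELLS_PER_SAMPLE))
    if "panel" in cols:
        panel = df[cols["panel"]].fillna("none").to_numpy(dtype=object)
        bad = set(panel) - set(PANEL_LABELS)
        if bad:
            raise ValueError(f"{path}: unknown panel labels {sorted(bad)}")
    else:
        panel = np.full(len(sample_ids), "none", dtype=object)
    return cells, panel


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return genes


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_metadata(path, config: dict, seed=None) -> dict:
    """Write the auditable run-metadata JSON next to the results."""
    from . import __version__

    meta = {
        "tool": "crisphi",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    return meta


def write_results_tsv(path, frame: pd.DataFrame, config: dict) -> None:
    """Write a per-gene results table with the config hash in a header comment."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# crisphi config_hash={config_hash(config)}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")
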