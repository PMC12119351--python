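"""Quality-control filters for patch-seq count matrices.

Cell-level filter: cells whose total reads or detected-gene count fall more
than three (unscaled) median absolute deviations below the respective median
are excluded.  Gene-level filter after counts-per-million normalisation:
a gene is kept when it reaches CPM > 15 in at least 5 cells and its mean
CPM across all cells exceeds 4.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .config import DEFAULTS

__all__ = ["mad_cell_filter", "cpm", "gene_filter", "qc_pipeline"]


def _mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation (no 1.4826 normality factor)."""
    return float(np.median(np.abs(x - np.median(x))))


def mad_cell_filter(
    reads_per_cell,
    genes_per_cell,
    mad_factor: float = DEFAULTS.qc_mad_factor,
) -> np.ndarray:
    """One-sided robust cell filter.

    Keep a cell iff reads >= median(reads) - 3*MAD(reads) AND detected
    genes >= median(genes) - 3*MAD(genes).  The cut is lower-sided only:
    unusually deep cells are not penalised.
    """
    reads = np.asarray(reads_per_cell, dtype=float)
    genes = np.asarray(genes_per_cell, dtype=float)
    if reads.size < 3:
        raise ValueError("need at least 3 cells")
    keep_r = reads >= np.median(reads) - mad_factor * _mad(reads)
    keep_g = genes >= np.median(genes) - mad_factor * _mad(genes)
    return keep_r & keep_g


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalisation of a gene x cell count matrix."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero-total cell(s): {bad}")
    return counts / totals * 1e6


def gene_filter(
    cpm_matrix: pd.DataFrame,
    min_cells: int = DEFAULTS.qc_gene_min_cells,
    cpm_min: float = DEFAULTS.qc_gene_cpm_min,
    mean_cpm_min: float = DEFAULTS.qc_gene_mean_cpm_min,
) -> pd.Series:
    """Gene-inclusion mask on a gene x cell CPM matrix.

    Keep a gene iff it has CPM strictly above ``cpm_min`` in at least
    ``min_cells`` cells and its mean CPM across all cells is strictly above
    ``mean_cpm_min``.
    """
    n_expressing = (cpm_matrix > cpm_min).sum(axis=1)
    mean_cpm = cpm_matrix.mean(axis=1)
    return (n_expressing >= min_cells) & (mean_cpm > mean_cpm_min)


def qc_pipeline(
    counts: pd.DataFrame,
) -> Tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Full QC: MAD cell filter, CPM, gene filter.

    Returns the filtered count matrix plus the cell and gene masks (cell
    mask indexed like the input columns, gene mask like the rows that
    survive on the filtered cells).
    """
    reads = counts.sum(axis=0).to_numpy()
    genes = (counts > 0).sum(axis=0).to_numpy()
    cell_mask = mad_cell_filter(reads, genes)
    kept = counts.loc[:, counts.columns[cell_mask]]
    gmask = gene_filter(cpm(kept))
    return kept.loc[gmask], cell_mask, gmask
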