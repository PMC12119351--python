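"""Null-distribution cell calling for fluorescent in situ hybridization.

Each segmented nucleus (DAPI ROI) contributes a sample of pixel
intensities.  A *null distribution* — the pooled, bin-normalised intensity
histogram of cells putatively negative for the targeted mRNA — is built
first; each cell's own normalised histogram is then compared to the null by
Pearson correlation.  A cell with R < 0.85 is called positive.  The
percentage of pixels above a background threshold (a high quantile of the
null) is reported alongside.

Binning (64 bins over the observed intensity range by default) and the
putative-negative selector (lowest decile of mean intensity by default) are
pinned in config and reported with results, since R depends on both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULTS

__all__ = [
    "CellIntensitySet",
    "NullDistribution",
    "FishCall",
    "lowest_decile_selector",
    "build_null",
    "cell_R",
    "call_cells",
    "cells_from_labeled_image",
    "cells_from_pixel_table",
]


@dataclass(frozen=True)
class CellIntensitySet:
    """Pixel-intensity sample within one nucleus mask."""

    cell_id: str
    pixel_intensities: np.ndarray

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_intensities)

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.pixel_intensities))


@dataclass(frozen=True)
class NullDistribution:
    """Pooled normalised intensity histogram of putatively negative cells."""

    bin_edges: np.ndarray
    density: np.ndarray  # normalised to sum 1
    source_cell_ids: Tuple[str, ...]
    background_intensity: float  # quantile of the pooled null pixels


@dataclass(frozen=True)
class FishCall:
    cell_id: str
    R: float
    positive: bool
    pct_positive_pixels: float
    mean_intensity: float


def lowest_decile_selector(cells: Sequence[CellIntensitySet]) -> List[CellIntensitySet]:
    """Default putative-negative selector: lowest decile of mean intensity."""
    means = np.array([c.mean_intensity for c in cells])
    cut = np.quantile(means, 0.10)
    picked = [c for c in cells if c.mean_intensity <= cut]
    return picked


def build_null(
    cells: Sequence[CellIntensitySet],
    selector: Optional[
        Callable[[Sequence[CellIntensitySet]], List[CellIntensitySet]]
    ] = None,
    n_bins: int = DEFAULTS.fish_n_bins,
    intensity_range: Optional[Tuple[float, float]] = None,
    background_quantile: float = DEFAULTS.fish_background_quantile,
    min_cells: int = 10,
) -> NullDistribution:
    """Build the null distribution from putatively negative cells.

    ``intensity_range`` defaults to the full observed range over *all* cells
    so the bin grid is shared between the null and every cell histogram.
    """
    if selector is None:
        selector = lowest_decile_selector
    picked = selector(cells)
    if len(picked) == 0:
        raise ValueError("negative-cell selector returned no cells")
    if len(picked) < min_cells:
        raise ValueError(
            f"selector yielded {len(picked)} cells; need >= {min_cells}"
        )
    if intensity_range is None:
        all_pix = np.concatenate([np.asarray(c.pixel_intensities) for c in cells])
        intensity_range = (float(all_pix.min()), float(all_pix.max()))
    edges = np.linspace(intensity_range[0], intensity_range[1], n_bins + 1)
    pooled = np.concatenate([np.asarray(c.pixel_intensities) for c in picked])
    counts, _ = np.histogram(pooled, bins=edges)
    density = counts / counts.sum()
    return NullDistribution(
        bin_edges=edges,
        density=density,
        source_cell_ids=tuple(c.cell_id for c in picked),
        background_intensity=float(np.quantile(pooled, background_quantile)),
    )


def cell_R(cell: CellIntensitySet, null: NullDistribution) -> float:
    """Pearson correlation of the cell's normalised histogram with the null.

    Returns NaN when either histogram has zero variance.
    """
    counts, _ = np.histogram(cell.pixel_intensities, bins=null.bin_edges)
    if counts.sum() == 0:
        return float("nan")
    h = counts / counts.sum()
    if np.std(h) == 0 or np.std(null.density) == 0:
        return float("nan")
    return float(np.corrcoef(h, null.density)[0, 1])


def call_cells(
    cells: Sequence[CellIntensitySet],
    null: NullDistribution,
    threshold: float = DEFAULTS.fish_r_threshold,
) -> List[FishCall]:
    """Call every cell positive/negative for the targeted mRNA.

    Positive iff R is strictly below ``threshold`` (R exactly at the
    threshold is negative).  ``pct_positive_pixels`` is the percentage of
    the cell's pixels exceeding the null's background intensity.
    """
    calls = []
    for cell in cells:
        r = cell_R(cell, null)
        pix = np.asarray(cell.pixel_intensities)
        pct = 100.0 * float(np.mean(pix > null.background_intensity))
        calls.append(
            FishCall(
                cell_id=cell.cell_id,
                R=r,
                positive=bool(np.isfinite(r) and r < threshold),
                pct_positive_pixels=pct,
                mean_intensity=cell.mean_intensity,
            )
        )
    return calls


def cells_from_labeled_image(
    image: np.ndarray,
    labels: np.ndarray,
    exclude: Sequence[int] = (),
    min_pixels: int = 50,
) -> List[CellIntensitySet]:
    """Extract per-cell pixel sets from a greyscale image + label mask.

    ``labels`` holds one integer per pixel (0 = background); manually
    curated ROI removals are passed as ``exclude`` label ids.  Cells with
    fewer than ``min_pixels`` pixels are dropped.
    """
    if image.shape != labels.shape:
        raise ValueError("image and label mask must have equal shape")
    out = []
    excl = set(int(e) for e in exclude)
    for lab in np.unique(labels):
        if lab == 0 or int(lab) in excl:
            continue
        pix = image[labels == lab].astype(float)
        if pix.size < min_pixels:
            continue
        out.append(CellIntensitySet(cell_id=str(int(lab)), pixel_intensities=pix))
    return out


def cells_from_pixel_table(df: pd.DataFrame, min_pixels: int = 50) -> List[CellIntensitySet]:
    """Build cell sets from a long-form table with cell_id, intensity columns."""
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        pix = grp["intensity"].to_numpy(dtype=float)
        if pix.size < min_pixels:
            continue
        out.append(CellIntensitySet(cell_id=str(cid), pixel_intensities=pix))
    return out


def calls_df(calls: Sequence[FishCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in calls],
            "R": [c.R for c in calls],
            "positive": [c.positive for c in calls],
            "pct_positive_pixels": [c.pct_positive_pixels for c in calls],
            "mean_intensity": [c.mean_intensity for c in calls],
        }
    )
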