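"""Peri-event classification of units into IR / DR / NR response types.

For each unit and motif, per-event firing rates are computed in a pre-event
window (-3 to 0 s) and an event window (0 to 3 s) relative to event onset.
The paired rates are compared with a two-sided Wilcoxon signed-rank test:
IR (increased response) when p < 0.05 and the event rate exceeds the
pre-event rate, DR (decreased response) when p < 0.05 with the opposite
direction, NR otherwise.  Group-level IR/DR/NR proportions are compared with
a chi-squared test, Bonferroni-corrected across motifs.

The signed-rank p value is exact — computed from the full null distribution
of the positive-rank sum over signed (possibly tied) ranks — for up to 25
non-zero differences, and uses a normal approximation with continuity and
tie correction above that.  Zero differences are dropped before ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULTS

__all__ = [
    "PairedEventRates",
    "ResponseCall",
    "peri_event_rates",
    "wilcoxon_signed_rank",
    "classify_response",
    "compare_proportions",
    "rate_duration_correlation",
]

EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedEventRates:
    """Per-event pre/post firing rates (spikes/s) for one unit and motif."""

    unit_id: str
    motif: str
    pre_rates: np.ndarray
    post_rates: np.ndarray
    overlapping: bool = False  # any window overlaps an adjacent event

    @property
    def n_events(self) -> int:
        return len(self.pre_rates)


@dataclass(frozen=True)
class ResponseCall:
    unit_id: str
    motif: str
    cls: Literal["IR", "DR", "NR"]
    p_value: float
    n_events: int


def peri_event_rates(
    spikes_s: Sequence[float],
    onsets_s: Sequence[float],
    pre: Tuple[float, float] = DEFAULTS.response_pre_window,
    post: Tuple[float, float] = DEFAULTS.response_post_window,
    unit_id: str = "",
    motif: str = "",
) -> PairedEventRates:
    """Pre/post firing rates around each event onset.

    Events whose pre window starts before the session (onset closer to 0 than
    the pre-window span) are dropped with a warning.  Overlap of analysis
    windows between back-to-back events is allowed but flagged.
    """
    spikes = np.asarray(spikes_s, dtype=float)
    onsets = np.asarray(onsets_s, dtype=float)
    keep = onsets + pre[0] >= 0
    if not np.all(keep):
        warnings.warn(
            f"dropped {int(np.sum(~keep))} event(s) too close to session start"
        )
        onsets = onsets[keep]
    pre_len = pre[1] - pre[0]
    post_len = post[1] - post[0]
    pre_n = np.searchsorted(spikes, onsets + pre[1]) - np.searchsorted(
        spikes, onsets + pre[0]
    )
    post_n = np.searchsorted(spikes, onsets + post[1]) - np.searchsorted(
        spikes, onsets + post[0]
    )
    overlap = bool(onsets.size > 1 and np.any(np.diff(onsets) < post[1] - pre[0]))
    return PairedEventRates(
        unit_id=unit_id,
        motif=motif,
        pre_rates=pre_n / pre_len,
        post_rates=post_n / post_len,
        overlapping=overlap,
    )


def _signed_rank_exact_p(r2: np.ndarray, w_plus2: float) -> float:
    """Exact two-sided p for the positive-rank sum, ranks doubled to ints.

    Builds the full null distribution of W+ over all 2^n sign assignments by
    dynamic programming (polynomial product), which handles tied (mid)ranks
    exactly.
    """
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w_plus2))
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    min_n: int = 1,
) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on per-event (post - pre).

    Returns ``(W, p)`` with ``W = min(W+, W-)``.  Zero differences are
    dropped; if all differences are zero (or fewer than ``min_n`` remain),
    p = 1.  Exact null for up to 25 non-zero differences, normal
    approximation with continuity and tie correction above.
    """
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < max(min_n, 1):
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= EXACT_MAX_N:
        r2 = np.round(2 * ranks).astype(int)  # midranks are half-integers
        p = _signed_rank_exact_p(r2, 2 * w_plus)
        return w, p
    mu = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if var <= 0:
        return w, 1.0
    # continuity correction: shrink |W+ - mu| by 0.5
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def classify_response(
    pairs: PairedEventRates,
    alpha: float = DEFAULTS.response_alpha,
    direction: Literal["mean", "median"] = "mean",
) -> ResponseCall:
    """IR/DR/NR call for one unit x motif from its paired event rates."""
    w, p = wilcoxon_signed_rank(pairs.pre_rates, pairs.post_rates)
    agg = np.mean if direction == "mean" else np.median
    cls = "NR"
    if p < alpha:
        if agg(pairs.post_rates) > agg(pairs.pre_rates):
            cls = "IR"
        elif agg(pairs.post_rates) < agg(pairs.pre_rates):
            cls = "DR"
    return ResponseCall(
        unit_id=pairs.unit_id,
        motif=pairs.motif,
        cls=cls,
        p_value=p,
        n_events=pairs.n_events,
    )


def compare_proportions(
    table: pd.DataFrame | np.ndarray,
    n_comparisons: int = 1,
) -> Dict[str, float]:
    """Chi-squared test on a group x response-class count table.

    Returns chi2, raw p and the Bonferroni-adjusted p
    (``min(1, p * n_comparisons)``).  No Yates continuity correction is
    applied.  Groups with zero total are rejected.
    """
    counts = np.asarray(table, dtype=float)
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("each group must have a non-zero total count")
    # drop all-zero response classes so expected counts are well defined
    counts = counts[:, counts.sum(axis=0) > 0]
    if counts.shape[1] < 2:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return {
        "chi2": float(chi2),
        "p": float(p),
        "p_bonferroni": float(min(1.0, p * n_comparisons)),
    }


def rate_duration_correlation(
    mean_rates: Sequence[float],
    time_in_motif_s: Sequence[float],
) -> Tuple[float, float]:
    """Spearman correlation of per-motif firing rate vs total motif time.

    Returns ``(rho, p)``; with constant input the correlation is undefined
    and ``(nan, nan)`` is returned.
    """
    r = np.asarray(mean_rates, dtype=float)
    t = np.asarray(time_in_motif_s, dtype=float)
    if r.size < 4:
        raise ValueError("need at least 4 motif points")
    if np.all(r == r[0]) or np.all(t == t[0]):
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(r, t)
    return float(rho), float(p)


def call_table(calls: List[ResponseCall]) -> pd.DataFrame:
    """Tidy per-unit call table."""
    return pd.DataFrame(
        {
            "unit_id": [c.unit_id for c in calls],
            "motif": [c.motif for c in calls],
            "class": [c.cls for c in calls],
            "p_value": [c.p_value for c in calls],
            "n_events": [c.n_events for c in calls],
        }
    )
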