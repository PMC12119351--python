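"""Fluorescence-trace processing for neuropeptide-sensor recordings.

Covers the three recording regimes of the study:

* **slice imaging** — reference-ROI division to dF/F, photobleach correction
  by excising the stimulation window, smoothing the remainder, fitting a
  polynomial trendline across the gap and subtracting it, then trapezoidal
  AUC over the stimulation window;
* **head-fixed photometry** — per-trial z-scoring against a pre-stimulation
  baseline and AUC in fixed windows (baseline -3..-1 s, stimulation 0..2 s,
  post-stimulation 3..5 s relative to laser onset);
* **pharmacology injections** — slow-timescale detrend and z-score against
  the -500..0 s pre-injection baseline, AUC over 1500..2000 s post
  injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .config import AUCWindows

__all__ = [
    "Trace",
    "AUCWindows",
    "roi_normalize",
    "detrend_excise",
    "trapezoid_auc",
    "zscore_peri_event",
    "injection_response",
]


@dataclass
class Trace:
    """Uniformly sampled fluorescence signal.

    ``f`` may be raw fluorescence or dF/F; operations state which they
    expect.  ``stim_onsets_s``/``stim_duration_s`` and ``injection_time_s``
    are optional experiment markers.
    """

    t_s: np.ndarray
    f: np.ndarray
    fs: float
    stim_onsets_s: Tuple[float, ...] = field(default_factory=tuple)
    stim_duration_s: float = 0.0
    injection_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t_s.shape != self.f.shape:
            raise ValueError("t_s and f must have equal length")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("trace contains non-finite values")
        if self.t_s.size > 1:
            dt = np.diff(self.t_s)
            if np.any(np.abs(dt - 1.0 / self.fs) > 0.01 / self.fs):
                raise ValueError("trace is not uniformly sampled at fs")


def roi_normalize(
    signal: Trace, reference: Trace, prestim_end_s: Optional[float] = None
) -> Trace:
    """Reference-ROI motion/illumination correction to dF/F.

    The signal is divided by the reference ROI sample-by-sample (a
    multiplicative common-mode artifact cancels exactly), then converted to
    dF/F against the mean ratio before ``prestim_end_s`` (default: first
    stimulation onset, else the whole trace).
    """
    if signal.t_s.shape != reference.t_s.shape or not np.allclose(
        signal.t_s, reference.t_s
    ):
        raise ValueError("signal and reference must share one time grid")
    if np.any(reference.f <= 0):
        raise ValueError("reference ROI contains non-positive values")
    ratio = signal.f / reference.f
    if prestim_end_s is None:
        prestim_end_s = signal.stim_onsets_s[0] if signal.stim_onsets_s else None
    base = ratio if prestim_end_s is None else ratio[signal.t_s < prestim_end_s]
    if base.size == 0 or np.mean(base) == 0:
        raise ValueError("cannot form a baseline for dF/F")
    dff = ratio / np.mean(base) - 1.0
    return Trace(
        t_s=signal.t_s,
        f=dff,
        fs=signal.fs,
        stim_onsets_s=signal.stim_onsets_s,
        stim_duration_s=signal.stim_duration_s,
        injection_time_s=signal.injection_time_s,
    )


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centred moving average with odd (anti-symmetric) end reflection.

    Odd reflection preserves linear trends exactly at the ends, so smoothing
    introduces no edge bias into a subsequent polynomial fit.
    """
    if n <= 1 or x.size < 2:
        return x
    h_lo, h_hi = n // 2, n - 1 - n // 2
    k_lo, k_hi = min(h_lo, x.size - 1), min(h_hi, x.size - 1)
    pad_lo = 2 * x[0] - x[1 : k_lo + 1][::-1]
    pad_hi = 2 * x[-1] - x[-k_hi - 1 : -1][::-1]
    if k_lo < h_lo:
        pad_lo = np.concatenate([np.full(h_lo - k_lo, pad_lo[0] if pad_lo.size else x[0]), pad_lo])
    if k_hi < h_hi:
        pad_hi = np.concatenate([pad_hi, np.full(h_hi - k_hi, pad_hi[-1] if pad_hi.size else x[-1])])
    kernel = np.ones(n) / n
    return np.convolve(np.concatenate([pad_lo, x, pad_hi]), kernel, mode="valid")


def _smooth_segments(x: np.ndarray, keep: np.ndarray, n: int) -> np.ndarray:
    """Smooth each contiguous retained run separately (no mixing across the
    excised gap)."""
    out = np.empty(int(keep.sum()))
    pos = 0
    idx = np.flatnonzero(keep)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [idx.size]])
    for s, e in zip(starts, ends):
        out[pos : pos + e - s] = _moving_average(x[idx[s:e]], n)
        pos += e - s
    return out


def detrend_excise(
    dff: Trace,
    excise_window_s: Tuple[float, float],
    smooth_span_s: float = 1.0,
    poly_order: int = 3,
) -> Trace:
    """Photobleach correction with stimulation-window excision.

    Samples inside ``excise_window_s`` (absolute trace time) are excluded;
    the remaining dF/F is smoothed with a ``smooth_span_s`` moving average, a
    polynomial of ``poly_order`` is fit to the smoothed retained samples and
    evaluated across the whole trace (bridging the excised gap), and this
    trendline is subtracted from the original unsmoothed dF/F.
    """
    lo, hi = excise_window_s
    keep = (dff.t_s < lo) | (dff.t_s > hi)
    n_keep = int(keep.sum())
    if n_keep <= poly_order:
        raise ValueError("too few retained samples for the polynomial order")
    span = max(1, int(round(smooth_span_s * dff.fs)))
    if span % 2 == 0:
        span += 1  # odd window: centred average introduces no phase shift
    smooth = _smooth_segments(dff.f, keep, span)
    # centre/scale the time axis for a well-conditioned fit
    t0, tsc = dff.t_s.mean(), max(dff.t_s.std(), 1e-12)
    coef = np.polyfit((dff.t_s[keep] - t0) / tsc, smooth, poly_order)
    trend = np.polyval(coef, (dff.t_s - t0) / tsc)
    return Trace(
        t_s=dff.t_s,
        f=dff.f - trend,
        fs=dff.fs,
        stim_onsets_s=dff.stim_onsets_s,
        stim_duration_s=dff.stim_duration_s,
        injection_time_s=dff.injection_time_s,
    )


def trapezoid_auc(trace: Trace, window_s: Tuple[float, float]) -> float:
    """Composite trapezoidal integral of the trace over ``window_s``.

    Partial end intervals are linearly interpolated so the integral covers
    the window exactly.
    """
    lo, hi = window_s
    if hi <= lo:
        raise ValueError("window must be non-degenerate")
    if lo < trace.t_s[0] - 1e-9 or hi > trace.t_s[-1] + 1e-9:
        raise ValueError("window extends outside the trace")
    inside = (trace.t_s > lo) & (trace.t_s < hi)
    t = np.concatenate([[lo], trace.t_s[inside], [hi]])
    f_lo = np.interp(lo, trace.t_s, trace.f)
    f_hi = np.interp(hi, trace.t_s, trace.f)
    f = np.concatenate([[f_lo], trace.f[inside], [f_hi]])
    return float(np.trapezoid(f, t))


def zscore_peri_event(
    trace: Trace,
    onsets_s: Sequence[float],
    analysis_window_s: Tuple[float, float] = (-10.0, 30.0),
    baseline_window_s: Tuple[float, float] = (-10.0, 0.0),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial z-scored peri-event matrix.

    Each trial is z-scored against its own baseline window (mean/sd of the
    samples in ``baseline_window_s`` relative to onset).  Returns
    ``(rel_time, trials, mean, sem)`` where ``trials`` is
    (n_trials, n_samples); trials with zero baseline s.d. are dropped.
    """
    lo, hi = analysis_window_s
    n_lo = int(round(lo * trace.fs))
    n_hi = int(round(hi * trace.fs))
    rel_t = np.arange(n_lo, n_hi + 1) / trace.fs
    bl = (rel_t >= baseline_window_s[0]) & (rel_t <= baseline_window_s[1])
    rows = []
    for onset in onsets_s:
        i0 = int(round(onset * trace.fs)) - int(round(trace.t_s[0] * trace.fs))
        sl = slice(i0 + n_lo, i0 + n_hi + 1)
        if sl.start < 0 or sl.stop > trace.f.size:
            raise ValueError(f"onset {onset} s: analysis window outside trace")
        seg = trace.f[sl]
        mu, sd = seg[bl].mean(), seg[bl].std(ddof=0)
        if sd == 0:
            import warnings

            warnings.warn(f"onset {onset} s: zero baseline s.d.; trial dropped")
            continue
        rows.append((seg - mu) / sd)
    trials = np.asarray(rows)
    if trials.size == 0:
        raise ValueError("no usable trials")
    mean = trials.mean(axis=0)
    sem = trials.std(axis=0, ddof=1) / np.sqrt(trials.shape[0]) if trials.shape[0] > 1 else np.zeros_like(mean)
    return rel_t, trials, mean, sem


def peri_event_aucs(
    rel_t: np.ndarray, mean_z: np.ndarray, windows: AUCWindows = AUCWindows()
) -> dict:
    """Baseline / stimulation / post-stimulation AUCs of a mean z trace."""
    fs = 1.0 / np.median(np.diff(rel_t))
    tr = Trace(t_s=rel_t, f=mean_z, fs=fs)
    return {
        "auc_baseline": trapezoid_auc(tr, windows.baseline),
        "auc_stim": trapezoid_auc(tr, windows.stim),
        "auc_post": trapezoid_auc(tr, windows.post),
    }


def injection_response(
    trace: Trace,
    injection_time_s: Optional[float] = None,
    windows: AUCWindows = AUCWindows(),
    detrend: bool = True,
) -> Tuple[float, float]:
    """Slow injection-response quantification.

    Aligns to the injection timepoint, linearly detrends using the
    pre-injection baseline segment, z-scores against that baseline, and
    returns the trapezoidal AUC of z over the baseline (-500..0 s) and
    post-injection (1500..2000 s) windows.
    """
    t0 = injection_time_s if injection_time_s is not None else trace.injection_time_s
    if t0 is None:
        raise ValueError("injection time not provided")
    rel = trace.t_s - t0
    bl_lo, bl_hi = windows.injection_baseline
    po_lo, po_hi = windows.injection_post
    if rel[0] > bl_lo or rel[-1] < po_hi:
        raise ValueError("trace does not cover the injection analysis windows")
    base = (rel >= bl_lo) & (rel <= bl_hi)
    f = trace.f.copy()
    if detrend:
        coef = np.polyfit(rel[base], f[base], 1)
        f = f - np.polyval(coef, rel)
    mu, sd = f[base].mean(), f[base].std(ddof=0)
    if sd == 0:
        raise ValueError("zero baseline s.d.")
    z = (f - mu) / sd
    ztr = Trace(t_s=rel, f=z, fs=trace.fs)
    return (
        trapezoid_auc(ztr, (bl_lo, bl_hi)),
        trapezoid_auc(ztr, (po_lo, po_hi)),
    )
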