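"""Feeding-bout detection from piezo food-cup sensor activations.

A feeding bout is a chain of at least two sensor activations in which no
inter-activation interval exceeds 6 s; an interval strictly larger than 6 s
breaks the chain.  Total feeding time is the summed bout duration
(last minus first activation of each bout; no tail is appended after the
final activation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .config import DEFAULTS

__all__ = ["Bout", "FeedingBouts", "merge_bouts", "align_clock"]


@dataclass(frozen=True)
class Bout:
    start_s: float
    end_s: float
    n_activations: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FeedingBouts:
    bouts: Tuple[Bout, ...]

    @property
    def total_feeding_time_s(self) -> float:
        return float(sum(b.duration_s for b in self.bouts))


def merge_bouts(
    activation_times_s: Sequence[float],
    max_gap_s: float = DEFAULTS.piezo_max_gap_s,
    min_activations: int = DEFAULTS.piezo_min_activations,
) -> FeedingBouts:
    """Greedy left-to-right chaining of activations into feeding bouts.

    Consecutive activations with a gap <= ``max_gap_s`` join one chain (a gap
    of exactly 6 s still joins); chains with at least ``min_activations``
    members become bouts.  Input must be sorted.
    """
    t = np.asarray(activation_times_s, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("activation times must be sorted")
    bouts: List[Bout] = []
    i = 0
    while i < t.size:
        j = i
        while j + 1 < t.size and t[j + 1] - t[j] <= max_gap_s:
            j += 1
        if j - i + 1 >= min_activations:
            bouts.append(Bout(float(t[i]), float(t[j]), j - i + 1))
        i = j + 1
    return FeedingBouts(tuple(bouts))


def align_clock(
    ttl_device_s: Sequence[float],
    ttl_reference_s: Sequence[float],
) -> Tuple[float, float, float]:
    """Least-squares affine map device->reference from matched TTL pairs.

    Returns ``(offset_s, slope, rms_residual_s)``; reference ~= slope*device
    + offset.  Needs at least two pairs for the slope (with one pair the
    slope is fixed at 1 and only the offset is estimated).
    """
    d = np.asarray(ttl_device_s, dtype=float)
    r = np.asarray(ttl_reference_s, dtype=float)
    if d.size != r.size:
        raise ValueError("matched TTL lists must have equal length")
    if d.size == 0:
        raise ValueError("need at least one TTL pair")
    if d.size == 1 or np.ptp(d) == 0:
        slope = 1.0
        offset = float(np.mean(r - d))
    else:
        slope, offset = np.polyfit(d, r, 1)
    resid = r - (slope * d + offset)
    rms = float(np.sqrt(np.mean(resid**2)))
    return float(offset), float(slope), rms
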