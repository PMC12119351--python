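"""Behavioural assay quantification.

Food consumption per trial (cup-weight difference), caloric intake from the
per-gram nutrition table, real-time place-preference (RTPP) zone occupancy
with the 10-min stimulation-side swap, and open-field centre time (33x33 cm
inner box of a 50x50 cm chamber).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "NUTRITION_KCAL_PER_G",
    "TrialRecord",
    "consumption",
    "caloric_intake",
    "home_cage_weekly",
    "rtpp_times",
    "centre_time",
]

# kcal per gram of food, from the supplier-declared nutritional values
NUTRITION_KCAL_PER_G: Dict[str, float] = {
    "jelly": 2.5,
    "butter": 7.14,
    "peanut_butter": 6.39,
    "chocolate": 4.88,
    "regular_chow": 3.02,
    "high_fat_chow": 5.24,
    "water": 0.0,
}

TRIAL_TEMPLATE = ("habituation", "primed", "OFF", "ON", "OFF")


@dataclass(frozen=True)
class TrialRecord:
    session_id: str
    trial_index: int
    trial_kind: str  # habituation | primed | OFF | ON
    food_type: str
    cup_weight_pre_g: float
    cup_weight_post_g: float
    duration_min: float = 15.0


def consumption(trial: TrialRecord) -> float:
    """Grams consumed: pre minus post cup weight, clipped at zero.

    A post weight above pre (spillage/condensation) is clipped to 0 g with a
    warning rather than counted as negative eating.
    """
    grams = trial.cup_weight_pre_g - trial.cup_weight_post_g
    if grams < 0:
        warnings.warn(
            f"{trial.session_id} trial {trial.trial_index}: post weight exceeds "
            f"pre weight ({-grams:.3f} g); consumption clipped to 0"
        )
        return 0.0
    return float(grams)


def caloric_intake(
    grams: float,
    food_type: str,
    table: Optional[Dict[str, float]] = None,
) -> float:
    """kcal consumed: grams times the food's kcal/g."""
    if table is None:
        table = NUTRITION_KCAL_PER_G
    if food_type not in table:
        raise KeyError(f"unknown food type {food_type!r}")
    return float(grams) * table[food_type]


def home_cage_weekly(grams_per_cage: float, n_mice: int) -> float:
    """Weekly consumption normalised to grams per mouse."""
    if n_mice < 1:
        raise ValueError("cage occupancy must be >= 1")
    return float(grams_per_cage) / n_mice


def rtpp_times(
    x_cm: Sequence[float],
    fs: float,
    chamber_length_cm: float,
    neutral_band_cm: Tuple[float, float],
    initial_stim_side: str = "left",
    phase_switch_s: float = 600.0,
) -> Dict[str, Dict[str, float]]:
    """RTPP zone occupancy per phase with the stimulation-side swap.

    ``x_cm`` is the body-centre x coordinate along the chamber's long axis;
    the middle ``neutral_band_cm = (lo, hi)`` is the never-stimulated
    neutral area.  After ``phase_switch_s`` the stimulation side switches to
    the previously non-stimulated side.  Returns per-phase and pooled time
    (s) in stim / non_stim / neutral zones; zone times partition tracked
    time exactly (band edges inclusive to neutral).
    """
    x = np.asarray(x_cm, dtype=float)
    if np.any((x < 0) | (x > chamber_length_cm)):
        raise ValueError("trajectory leaves the chamber")
    lo, hi = neutral_band_cm
    frames = np.arange(x.size)
    in_phase2 = frames / fs >= phase_switch_s
    left = x < lo
    right = x > hi
    neutral = ~(left | right)
    stim_left_phase1 = initial_stim_side == "left"
    out: Dict[str, Dict[str, float]] = {}
    for phase, mask in (("phase1", ~in_phase2), ("phase2", in_phase2)):
        stim_is_left = stim_left_phase1 if phase == "phase1" else not stim_left_phase1
        stim = left if stim_is_left else right
        non = right if stim_is_left else left
        out[phase] = {
            "stim": float(np.sum(stim & mask)) / fs,
            "non_stim": float(np.sum(non & mask)) / fs,
            "neutral": float(np.sum(neutral & mask)) / fs,
        }
    out["pooled"] = {
        k: out["phase1"][k] + out["phase2"][k] for k in ("stim", "non_stim", "neutral")
    }
    return out


def centre_time(
    xy_cm: np.ndarray,
    fs: float,
    chamber_size_cm: float = 50.0,
    centre_box_cm: float = 33.0,
) -> float:
    """Open-field centre time: seconds with the body centre inside the
    centred ``centre_box_cm`` square (edges inclusive)."""
    xy = np.asarray(xy_cm, dtype=float)
    margin = (chamber_size_cm - centre_box_cm) / 2.0
    inside = (
        (xy[:, 0] >= margin)
        & (xy[:, 0] <= chamber_size_cm - margin)
        & (xy[:, 1] >= margin)
        & (xy[:, 1] <= chamber_size_cm - margin)
    )
    return float(np.sum(inside)) / fs
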