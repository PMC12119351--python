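"""Single source of truth for analysis defaults.

Every threshold used downstream lives here so that a pipeline run can emit a
complete provenance record.  All values are overridable per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple


@dataclass(frozen=True)
class MotifConfig:
    """Geometric and kinematic rules for behavioural motif deduction.

    Distances in cm, angles in degrees, velocities in cm/s.
    ``velocity_bins`` maps class name -> (low, high) with half-open
    lower-inclusive intervals partitioning [0, inf).
    """

    cup_radius_cm: float = 5.0
    rear_dist_cm: float = 2.0
    turn_angle_deg: float = 15.0
    velocity_bins: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "stopping": (0.0, 1.0),
            "walking": (1.0, 5.0),
            "trotting": (5.0, 10.0),
            "running": (10.0, float("inf")),
        }
    )
    exclusion_radius_cm: float = 7.0
    min_frames: int = 7
    likelihood_min: float = 0.85
    # centred moving-average span (s) applied to the body track before
    # differencing; per-frame differencing of raw tracking at 15 fps turns
    # sub-mm keypoint jitter into several cm/s of spurious speed
    velocity_smooth_s: float = 1.0


@dataclass(frozen=True)
class AUCWindows:
    """Fixed analysis windows (s) for fluorescence AUC quantification.

    Peri-stimulation windows are relative to stimulation onset; injection
    windows are relative to the injection timepoint.
    """

    baseline: Tuple[float, float] = (-3.0, -1.0)
    stim: Tuple[float, float] = (0.0, 2.0)
    post: Tuple[float, float] = (3.0, 5.0)
    injection_baseline: Tuple[float, float] = (-500.0, 0.0)
    injection_post: Tuple[float, float] = (1500.0, 2000.0)


@dataclass(frozen=True)
class Defaults:
    """Pipeline-wide scalar defaults."""

    optotag_n_shuffles: int = 10_000
    optotag_percentile: float = 99.9
    optotag_latency_max_ms: float = 8.0
    optotag_window_ms: float = 100.0
    optotag_bin_ms: float = 2.0
    piezo_max_gap_s: float = 6.0
    piezo_min_activations: int = 2
    response_pre_window: Tuple[float, float] = (-3.0, 0.0)
    response_post_window: Tuple[float, float] = (0.0, 3.0)
    response_alpha: float = 0.05
    fish_r_threshold: float = 0.85
    fish_n_bins: int = 64
    fish_background_quantile: float = 0.975
    qc_mad_factor: float = 3.0
    qc_gene_min_cells: int = 5
    qc_gene_cpm_min: float = 15.0
    qc_gene_mean_cpm_min: float = 4.0


DEFAULTS = Defaults()


def provenance() -> dict:
    """All default parameter values as a flat, loggable dict."""
    out = {f"defaults.{k}": v for k, v in asdict(DEFAULTS).items()}
    out.update({f"motif.{k}": v for k, v in asdict(MotifConfig()).items()})
    out.update({f"auc.{k}": v for k, v in asdict(AUCWindows()).items()})
    return out
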