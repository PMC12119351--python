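"""Ground-truthed synthetic sessions for every pipeline stage.

Each generator emulates one recording modality of the study at realistic
operating conditions — Poisson spike trains with event-locked rate steps and
short-latency light-evoked spikes, scripted arena trajectories that satisfy
the motif rules with margin, bout-structured piezo activations, fluorescence
traces with photobleaching / stimulation artifact / delayed transient, and
bimodal nucleus pixel-intensity mixtures — and returns the ground truth
needed to score the corresponding detector.

All generators are deterministic given (params, seed); random streams are
per-call ``numpy`` Generators so adding one call never shifts another's
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .motifs import ArenaConfig, PoseTrack
from .photometry import Trace

__all__ = [
    "SpikeSimParams",
    "PhotometrySimParams",
    "FishSimParams",
    "generate_spike_session",
    "generate_pose_session",
    "generate_piezo_train",
    "generate_photometry_trace",
    "generate_fish_dataset",
]


# ---------------------------------------------------------------------------
# spikes

@dataclass(frozen=True)
class SpikeSimParams:
    """Parameters of the synthetic single-unit spike generator.

    Rates in events/s, latencies in ms.  ``event_gain`` multiplies the
    baseline rate during the 3 s after each behavioural event onset;
    ``light_response_prob`` is the probability of one evoked spike per laser
    pulse at latency Normal(``light_latency_ms``, ``latency_jitter_ms``)
    truncated positive.
    """

    baseline_rate: float = 5.0
    event_gain: float = 1.0
    light_response_prob: float = 0.0
    light_latency_ms: float = 4.0
    latency_jitter_ms: float = 0.5
    refractory_ms: float = 1.0
    duration_s: float = 600.0

    def __post_init__(self) -> None:
        vals = (
            self.baseline_rate,
            self.event_gain,
            self.light_response_prob,
            self.light_latency_ms,
            self.latency_jitter_ms,
            self.refractory_ms,
            self.duration_s,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite spike simulation parameter")
        if self.baseline_rate < 0 or self.event_gain < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.light_response_prob <= 1:
            raise ValueError("light_response_prob must be in [0, 1]")
        if self.latency_jitter_ms < 0 or self.refractory_ms < 0:
            raise ValueError("jitter and refractory must be >= 0")
        if self.duration_s < 0:
            raise ValueError("duration must be >= 0")


def _piecewise_poisson(
    rng: np.random.Generator,
    segments: List[Tuple[float, float, float]],
) -> np.ndarray:
    """Sample a piecewise-homogeneous Poisson process; segments are
    (start, end, rate)."""
    times = []
    for lo, hi, rate in segments:
        if hi <= lo or rate <= 0:
            continue
        n = rng.poisson(rate * (hi - lo))
        times.append(lo + rng.random(n) * (hi - lo))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def generate_spike_session(
    params: SpikeSimParams,
    pulse_onsets_s: Sequence[float] = (),
    events: Sequence[Tuple[float, str]] = (),
    seed: int = 0,
    event_window_s: float = 3.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate one unit's spike train; returns ``(spikes_s, evoked_mask)``.

    Baseline spiking is homogeneous Poisson at ``baseline_rate`` with the
    rate multiplied by ``event_gain`` during ``event_window_s`` after each
    event onset.  Per laser pulse, with probability ``light_response_prob``,
    one evoked spike is added at a truncated-normal latency.  Refractory
    violations are resolved by deleting the later spike (evoked latencies of
    surviving evoked spikes are preserved).  ``evoked_mask`` flags which
    returned spikes are light-evoked.
    """
    rng = np.random.default_rng(seed)
    T = params.duration_s
    pulses = np.asarray(pulse_onsets_s, dtype=float)
    if pulses.size and (pulses.min() < 0 or pulses.max() > T):
        raise ValueError("pulses outside session duration")
    onsets = np.asarray([o for o, _ in events], dtype=float)
    if onsets.size and (onsets.min() < 0 or onsets.max() > T):
        raise ValueError("events outside session duration")

    # piecewise rate: baseline everywhere, scaled inside event windows
    edges = {0.0, T}
    for o in onsets:
        edges.add(float(o))
        edges.add(float(min(o + event_window_s, T)))
    grid = sorted(edges)
    segments = []
    for lo, hi in zip(grid[:-1], grid[1:]):
        mid = (lo + hi) / 2
        in_event = bool(onsets.size) and bool(
            np.any((onsets <= mid) & (mid < onsets + event_window_s))
        )
        rate = params.baseline_rate * (params.event_gain if in_event else 1.0)
        segments.append((lo, hi, rate))
    base = _piecewise_poisson(rng, segments)

    evoked_times: List[float] = []
    if pulses.size and params.light_response_prob > 0:
        fires = rng.random(pulses.size) < params.light_response_prob
        for p in pulses[fires]:
            lat = rng.normal(params.light_latency_ms, params.latency_jitter_ms)
            while lat <= 0:  # truncate to positive latency
                lat = rng.normal(params.light_latency_ms, params.latency_jitter_ms)
            t = p + lat / 1000.0
            if t <= T:
                evoked_times.append(t)
    ev = np.asarray(evoked_times)

    times = np.concatenate([base, ev])
    flags = np.concatenate(
        [np.zeros(base.size, dtype=bool), np.ones(ev.size, dtype=bool)]
    )
    order = np.argsort(times, kind="stable")
    times, flags = times[order], flags[order]

    # refractory: delete the later spike of any violating pair
    if times.size and params.refractory_ms > 0:
        ref = params.refractory_ms / 1000.0
        keep = np.ones(times.size, dtype=bool)
        last = -np.inf
        for i, t in enumerate(times):
            if t - last < ref:
                keep[i] = False
            else:
                last = t
        times, flags = times[keep], flags[keep]
    return times, flags


# ---------------------------------------------------------------------------
# pose

STATE_VOCAB = (
    "feeding_jelly",
    "feeding_chow",
    "empty_cup",
    "rearing",
    "turning",
    "stopping",
    "walking",
    "trotting",
    "running",
)

# nominal body speeds (cm/s), chosen at velocity-class midpoints with margin
STATE_SPEED = {"stopping": 0.0, "walking": 3.0, "trotting": 7.5, "running": 15.0}

# what the frame labeller should produce for each scripted state
STATE_TRUTH = {
    "feeding_jelly": "feeding",
    "feeding_chow": "feeding",
    "empty_cup": "empty_cup",
    "rearing": "rearing",
    "turning": "stopping",  # turning is counted on a separate channel
    "stopping": "stopping",
    "walking": "walking",
    "trotting": "trotting",
    "running": "running",
}

VELOCITY_STATES = {"stopping", "walking", "trotting", "running", "turning"}


def generate_pose_session(
    script: Sequence[Tuple[str, float]],
    arena: ArenaConfig = ArenaConfig(),
    fs: float = 15.0,
    noise_cm: float = 0.0,
    likelihood_dropout: float = 0.0,
    seed: int = 0,
    circle_radius_cm: Optional[float] = None,
    transition_blank_s: float = 1.0,
) -> Tuple[PoseTrack, List[Optional[str]]]:
    """Scripted arena session; returns ``(track, frame_truth_labels)``.

    Each scripted state is realised so its geometric definition holds with
    margin: feeding/empty — head 2 cm from the cup; rearing — head 0.5 cm
    from the body, far from both cups; velocity classes — motion at the
    class-midpoint speed along a circle around the arena centre, sized so
    the whole path (including the head, 3.5 cm ahead of the body) stays
    outside the 7-cm cup exclusion zone with margin.  Isotropic Gaussian
    jitter of ``noise_cm`` is added after placement.

    Ground-truth labels are None where the instantaneous velocity is not
    defined by the script: within ``transition_blank_s`` of the boundaries
    of every velocity-class segment, the frame-to-frame displacement (and
    any smoothed estimate of it) mixes motion across a scripted relocation
    or a speed step.  Proximity-defined states keep their truth right up to
    the boundary.  Frames dropped by the likelihood channel (rate
    ``likelihood_dropout``, likelihood drawn below 0.85) also get truth
    None.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    for state, dur in script:
        if state not in STATE_VOCAB:
            raise ValueError(f"unknown state {state!r}")
        if dur <= 0:
            raise ValueError("state durations must be positive")
    rng = np.random.default_rng(seed)
    centre = np.array(arena.chamber_size_cm) / 2.0
    cup_food = np.asarray(arena.cup_food_xy, dtype=float)
    cup_empty = np.asarray(arena.cup_empty_xy, dtype=float)
    min_cup_dist = min(
        np.linalg.norm(cup_food - centre), np.linalg.norm(cup_empty - centre)
    )
    head_lead = 3.5  # cm ahead of body: clear of the 2-cm rearing rule
    if circle_radius_cm is None:
        circle_r = min(12.0, min_cup_dist - 7.0 - head_lead - 1.0)
    else:
        circle_r = circle_radius_cm
    needs_path = any(s in VELOCITY_STATES for s, _ in script)
    if needs_path and circle_r < 1.0:
        raise ValueError(
            "arena too small: locomotion path would enter the cup exclusion zone"
        )

    nose, head, body, tail = [], [], [], []
    truth: List[Optional[str]] = []
    seg_bounds: List[Tuple[int, int, str]] = []
    phase = 0.0  # angular position on the locomotion circle

    def place_static(head_xy, body_xy, tail_xy, n, label):
        d = (head_xy - body_xy) / max(np.linalg.norm(head_xy - body_xy), 1e-9)
        for _ in range(n):
            head.append(head_xy.copy())
            body.append(body_xy.copy())
            tail.append(tail_xy.copy())
            nose.append(head_xy + d * 1.0)
            truth.append(label)

    for state, dur in script:
        n = int(round(dur * fs))
        start = len(truth)
        if state in ("feeding_jelly", "feeding_chow", "empty_cup"):
            cup = cup_food if state != "empty_cup" else cup_empty
            away = (centre - cup) / np.linalg.norm(centre - cup)
            head_xy = cup + away * 2.0  # inside the 5-cm rule with margin
            body_xy = cup + away * 5.0  # head-body 3 cm: not rearing
            tail_xy = cup + away * 8.0
            place_static(head_xy, body_xy, tail_xy, n, STATE_TRUTH[state])
        elif state == "rearing":
            body_xy = centre.copy()
            head_xy = centre + np.array([0.5, 0.0])  # < 2 cm: rearing
            tail_xy = centre + np.array([-3.0, 0.0])
            place_static(head_xy, body_xy, tail_xy, n, STATE_TRUTH[state])
        elif state == "turning":
            body_xy = centre.copy()
            tail_xy = centre - np.array([3.0, 0.0])  # body axis along +x
            ang = np.radians(30.0)  # 30 deg > 15-deg threshold
            head_xy = centre + head_lead * np.array([np.cos(ang), np.sin(ang)])
            place_static(head_xy, body_xy, tail_xy, n, STATE_TRUTH[state])
        else:  # velocity class on the central circle
            speed = STATE_SPEED[state]
            dphase = speed / circle_r / fs
            for k in range(n):
                if k > 0:
                    phase += dphase
                pos = centre + circle_r * np.array([np.cos(phase), np.sin(phase)])
                tang = np.array([-np.sin(phase), np.cos(phase)])
                body.append(pos)
                head.append(pos + tang * head_lead)
                tail.append(pos - tang * 3.0)
                nose.append(pos + tang * (head_lead + 1.0))
                truth.append(STATE_TRUTH[state])
        seg_bounds.append((start, len(truth), state))

    # blank velocity-defined truth near segment boundaries
    nb = int(round(transition_blank_s * fs))
    for start, end, state in seg_bounds:
        if state in VELOCITY_STATES and nb > 0:
            for f in range(start, min(start + nb, end)):
                truth[f] = None
            for f in range(max(end - nb, start), end):
                truth[f] = None

    n_frames = len(body)
    arrs = {
        "nose": np.asarray(nose),
        "head": np.asarray(head),
        "body": np.asarray(body),
        "tail": np.asarray(tail),
    }
    if noise_cm > 0:
        for k in arrs:
            arrs[k] = arrs[k] + rng.normal(0, noise_cm, size=arrs[k].shape)
    lik = {}
    drop = rng.random(n_frames) < likelihood_dropout
    for k in arrs:
        good = 0.85 + 0.15 * rng.random(n_frames)
        bad = 0.85 * rng.random(n_frames)
        lik[k] = np.where(drop, bad, good)
    for f in np.nonzero(drop)[0]:
        truth[f] = None
    track = PoseTrack(
        nose=arrs["nose"],
        head=arrs["head"],
        body=arrs["body"],
        tail=arrs["tail"],
        likelihood=lik,
        fs=fs,
    )
    return track, truth


# ---------------------------------------------------------------------------
# piezo

def generate_piezo_train(
    bouts: Sequence[Tuple[float, float]],
    intra_rate: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Bout-structured piezo activation timestamps.

    Each (start, end) bout gets guaranteed activations at its start and end
    plus Poisson activations at ``intra_rate`` inside; nothing is generated
    outside bouts.  Bouts must be non-overlapping.
    """
    if intra_rate <= 0:
        raise ValueError("intra_rate must be positive")
    ordered = sorted(bouts)
    for (s0, e0), (s1, _) in zip(ordered[:-1], ordered[1:]):
        if s1 < e0:
            raise ValueError("bouts overlap")
    rng = np.random.default_rng(seed)
    times = []
    for start, end in ordered:
        if end <= start:
            raise ValueError("bout end must exceed start")
        n = rng.poisson(intra_rate * (end - start))
        inner = start + rng.random(n) * (end - start)
        times.append(np.concatenate([[start], inner, [end]]))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


# ---------------------------------------------------------------------------
# photometry

@dataclass(frozen=True)
class PhotometrySimParams:
    """Synthetic fluorescence-trace parameters.

    The trace is bleach decay + per-stimulation square negative artifact +
    delayed exponential positive transient + white noise, in dF/F units.
    """

    fs: float = 20.0
    duration_s: float = 60.0
    bleach_amp: float = 0.2
    bleach_tau_s: float = 30.0
    bleach_amp2: float = 0.0
    bleach_tau2_s: float = 300.0
    artifact_amp: float = -0.05
    artifact_duration_s: float = 1.0
    transient_amp: float = 0.05
    transient_delay_s: float = 3.0
    transient_tau_s: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.bleach_tau_s <= 0 or self.bleach_tau2_s <= 0 or self.transient_tau_s <= 0:
            raise ValueError("taus must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def transient_auc_truth(params: PhotometrySimParams, window_s: float) -> float:
    """Closed-form AUC of one transient over [delay, delay + window]:
    A * tau * (1 - exp(-window/tau))."""
    return params.transient_amp * params.transient_tau_s * (
        1.0 - np.exp(-window_s / params.transient_tau_s)
    )


def generate_photometry_trace(
    params: PhotometrySimParams,
    stim_times_s: Sequence[float] = (),
    seed: int = 0,
) -> Tuple[Trace, List[float]]:
    """Synthetic dF/F trace; returns ``(trace, truth_auc_per_stim)``.

    Ground-truth AUC is the analytic integral of each transient over
    [delay, delay + 2*tau].
    """
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.fs)) + 1
    t = np.arange(n) / params.fs
    stims = np.asarray(stim_times_s, dtype=float)
    if stims.size and (stims.min() < 0 or stims.max() > params.duration_s):
        raise ValueError("stim times outside trace support")
    f = params.bleach_amp * np.exp(-t / params.bleach_tau_s) + params.bleach_amp2 * np.exp(
        -t / params.bleach_tau2_s
    )
    for s in stims:
        in_art = (t >= s) & (t < s + params.artifact_duration_s)
        f = f + params.artifact_amp * in_art
        dt = t - (s + params.transient_delay_s)
        f = f + np.where(dt >= 0, params.transient_amp * np.exp(-dt / params.transient_tau_s), 0.0)
    if params.noise_sd > 0:
        f = f + rng.normal(0, params.noise_sd, size=n)
    truth = [transient_auc_truth(params, 2 * params.transient_tau_s) for _ in stims]
    trace = Trace(
        t_s=t,
        f=f,
        fs=params.fs,
        stim_onsets_s=tuple(float(s) for s in stims),
        stim_duration_s=params.artifact_duration_s,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# FISH

@dataclass(frozen=True)
class FishSimParams:
    """Bimodal nucleus pixel-intensity mixture parameters (greyscale)."""

    null_mean: float = 30.0
    null_sd: float = 8.0
    pos_shift: float = 40.0
    pos_fraction: float = 0.5
    pixels_per_cell: int = 400
    max_intensity: float = 255.0

    def __post_init__(self) -> None:
        if self.null_sd <= 0:
            raise ValueError("null_sd must be positive")
        if not 0 <= self.pos_fraction <= 1:
            raise ValueError("pos_fraction must be in [0, 1]")
        if self.pixels_per_cell < 50:
            raise ValueError("pixels_per_cell must be >= 50")


def generate_fish_dataset(
    params: FishSimParams,
    n_negative: int,
    n_positive: int,
    seed: int = 0,
):
    """Synthetic FISH cells; returns ``(cells, labels)`` with labels True for
    positive cells.

    Negative cells draw all pixels from Normal(null_mean, null_sd) clipped to
    [0, max_intensity]; positive cells draw ``pos_fraction`` of pixels from
    the mode shifted up by ``pos_shift``.
    """
    from .fish import CellIntensitySet

    if n_negative < 1 or n_positive < 0:
        raise ValueError("cell counts must be >= 1 negative, >= 0 positive")
    rng = np.random.default_rng(seed)
    cells, labels = [], []
    for i in range(n_negative + n_positive):
        positive = i >= n_negative
        n_pix = params.pixels_per_cell
        pix = rng.normal(params.null_mean, params.null_sd, size=n_pix)
        if positive and params.pos_fraction > 0:
            n_pos = int(round(params.pos_fraction * n_pix))
            pix[:n_pos] += params.pos_shift
        pix = np.clip(pix, 0.0, params.max_intensity)
        cells.append(
            CellIntensitySet(
                cell_id=f"{'pos' if positive else 'neg'}_{i}",
                pixel_intensities=pix,
            )
        )
        labels.append(positive)
    return cells, labels
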