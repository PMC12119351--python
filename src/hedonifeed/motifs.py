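"""Behavioural motif deduction from pose-estimation keypoints.

Per-frame xy coordinates of nose, head, body centre and tail base (tracked at
15 frames/s in the source recordings) are converted into a per-frame motif
label and a list of motif events.  The rules, in priority order per frame:

1. *feeding* — head within 5 cm of the food cup;
2. *empty_cup* — head within 5 cm of the empty cup;
3. *rearing* — head–body distance below 2 cm;
4. a velocity class (*stopping* <1, *walking* 1–5, *trotting* 5–10,
   *running* >10 cm/s), suppressed when the head is within 7 cm of either
   cup to avoid confusion with the cup motifs.

Frames where any keypoint's tracking likelihood is below 0.85 are invalid:
they receive no label and break event continuity.  Motif occurrences shorter
than 7 frames (0.5 s) are discarded.  Head turns (head axis deviating more
than 15 degrees from the body axis) are counted per excursion on a separate
channel rather than segmented into timed events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import MotifConfig

__all__ = [
    "ArenaConfig",
    "PoseTrack",
    "MotifEvent",
    "MotifSegmentation",
    "filter_likelihood",
    "compute_velocity",
    "label_frames",
    "segment_events",
    "count_turns",
    "segment_track",
    "read_dlc_csv",
    "write_dlc_csv",
]

KEYPOINTS = ("nose", "head", "body", "tail")


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry and calibration.

    Coordinates are cm with the origin at the arena's lower-left corner.
    ``px_per_cm`` converts raw pixel tracks to cm (isotropic calibration).
    """

    chamber_size_cm: Tuple[float, float] = (25.0, 25.0)
    px_per_cm: float = 1.0
    cup_food_xy: Tuple[float, float] = (4.0, 4.0)
    cup_empty_xy: Tuple[float, float] = (21.0, 21.0)
    centre_box_cm: float = 33.0  # inner square side, open-field arenas

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        w, h = self.chamber_size_cm
        for cup in (self.cup_food_xy, self.cup_empty_xy):
            if not (0 <= cup[0] <= w and 0 <= cup[1] <= h):
                raise ValueError(f"cup {cup} outside chamber {self.chamber_size_cm}")


@dataclass
class PoseTrack:
    """Per-frame keypoint coordinates (cm) with tracking likelihoods.

    Arrays are (n_frames, 2) for coordinates and (n_frames,) per-keypoint
    likelihood in [0, 1].  ``valid`` marks frames usable for labelling; it is
    None until :func:`filter_likelihood` runs.
    """

    nose: np.ndarray
    head: np.ndarray
    body: np.ndarray
    tail: np.ndarray
    likelihood: dict  # keypoint name -> (n_frames,) array
    fs: float = 15.0
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.body)
        for name in KEYPOINTS:
            if len(getattr(self, name)) != n or len(self.likelihood[name]) != n:
                raise ValueError("keypoint arrays must share one length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.body)


@dataclass(frozen=True)
class MotifEvent:
    onset_frame: int
    offset_frame: int  # exclusive
    label: str


@dataclass
class MotifSegmentation:
    """Per-frame labels plus derived events and the session turn count."""

    frame_labels: List[Optional[str]]
    events: List[MotifEvent] = field(default_factory=list)
    turn_count: int = 0

    def events_df(self, fs: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset_frame / fs for e in self.events],
                "offset_s": [e.offset_frame / fs for e in self.events],
                "label": [e.label for e in self.events],
            }
        )


def filter_likelihood(
    track: PoseTrack, likelihood_min: float = MotifConfig().likelihood_min
) -> PoseTrack:
    """Mark frames invalid when any keypoint's likelihood is below threshold.

    The boundary is inclusive: likelihood exactly at the threshold keeps the
    frame.  Returns the track with its ``valid`` mask set.
    """
    valid = np.ones(track.n_frames, dtype=bool)
    for name in KEYPOINTS:
        valid &= np.asarray(track.likelihood[name]) >= likelihood_min
    track.valid = valid
    return track


def _smooth_positions(xy: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return xy
    pad_lo = np.repeat(xy[:1], w // 2, axis=0)
    pad_hi = np.repeat(xy[-1:], w - 1 - w // 2, axis=0)
    padded = np.concatenate([pad_lo, xy, pad_hi], axis=0)
    kernel = np.ones(w) / w
    out = np.empty_like(xy, dtype=float)
    for ax in range(xy.shape[1]):
        out[:, ax] = np.convolve(padded[:, ax], kernel, mode="valid")
    return out


def compute_velocity(
    track: PoseTrack, arena: ArenaConfig, smooth_s: float = 0.0
) -> np.ndarray:
    """Per-frame body-centre speed (cm/s); the first frame's speed is 0.

    ``smooth_s > 0`` applies a centred moving average to the body trajectory
    before differencing (edge-padded).  Smoothing leaves constant-velocity
    motion untouched but suppresses the spurious speed that per-frame
    differencing extracts from tracking jitter.
    """
    body = np.asarray(track.body, dtype=float)
    w = int(round(smooth_s * track.fs))
    if w % 2 == 0:
        w += 1 if w else 0
    body = _smooth_positions(body, w)
    disp = np.linalg.norm(np.diff(body, axis=0), axis=1)
    speed = np.concatenate([[0.0], disp * track.fs])
    return speed


def _velocity_class(speed: float, config: MotifConfig) -> str:
    for name, (lo, hi) in config.velocity_bins.items():
        if lo <= speed < hi:
            return name
    raise ValueError(f"speed {speed} not covered by velocity bins")


def label_frames(
    track: PoseTrack,
    arena: ArenaConfig,
    config: MotifConfig = MotifConfig(),
) -> List[Optional[str]]:
    """Assign at most one motif label per frame (None = invalid/suppressed)."""
    if track.valid is None:
        filter_likelihood(track, config.likelihood_min)
    speed = compute_velocity(track, arena, config.velocity_smooth_s)
    head = np.asarray(track.head, dtype=float)
    body = np.asarray(track.body, dtype=float)
    d_food = np.linalg.norm(head - np.asarray(arena.cup_food_xy), axis=1)
    d_empty = np.linalg.norm(head - np.asarray(arena.cup_empty_xy), axis=1)
    d_rear = np.linalg.norm(head - body, axis=1)

    labels: List[Optional[str]] = []
    for f in range(track.n_frames):
        if not track.valid[f]:
            labels.append(None)
            continue
        near_food = d_food[f] < config.cup_radius_cm
        near_empty = d_empty[f] < config.cup_radius_cm
        if near_food and near_empty:
            # tie: nearest cup wins so each frame has a unique label
            labels.append("feeding" if d_food[f] <= d_empty[f] else "empty_cup")
        elif near_food:
            labels.append("feeding")
        elif near_empty:
            labels.append("empty_cup")
        elif d_rear[f] < config.rear_dist_cm:
            labels.append("rearing")
        elif min(d_food[f], d_empty[f]) < config.exclusion_radius_cm:
            labels.append(None)  # too close to a plate for velocity motifs
        else:
            labels.append(_velocity_class(speed[f], config))
    return labels


def segment_events(
    frame_labels: Sequence[Optional[str]],
    min_frames: int = MotifConfig().min_frames,
) -> List[MotifEvent]:
    """Maximal runs of one label; runs shorter than ``min_frames`` dropped."""
    events: List[MotifEvent] = []
    start = 0
    n = len(frame_labels)
    while start < n:
        label = frame_labels[start]
        end = start + 1
        while end < n and frame_labels[end] == label:
            end += 1
        if label is not None and end - start >= min_frames:
            events.append(MotifEvent(start, end, label))
        start = end
    return events


def count_turns(
    track: PoseTrack,
    config: MotifConfig = MotifConfig(),
) -> int:
    """Number of head-turn excursions beyond the 15-degree threshold.

    Body orientation is the tail->body vector; head orientation is the
    body->head vector.  Each contiguous run of frames with unsigned angle
    above threshold counts once (rising-edge counting).  Frames with a
    degenerate (zero-length) orientation vector are skipped and do not break
    an excursion.
    """
    body = np.asarray(track.body, dtype=float)
    head = np.asarray(track.head, dtype=float)
    tail = np.asarray(track.tail, dtype=float)
    v_body = body - tail
    v_head = head - body
    nb = np.linalg.norm(v_body, axis=1)
    nh = np.linalg.norm(v_head, axis=1)
    ok = (nb > 0) & (nh > 0)
    cosang = np.full(len(body), np.nan)
    dot = np.einsum("ij,ij->i", v_body, v_head)
    cosang[ok] = np.clip(dot[ok] / (nb[ok] * nh[ok]), -1.0, 1.0)
    above = np.degrees(np.arccos(cosang[ok])) > config.turn_angle_deg
    # rising edges over the defined-angle frames
    return int(np.sum(above[1:] & ~above[:-1]) + (above[0] if above.size else 0))


def segment_track(
    track: PoseTrack,
    arena: ArenaConfig,
    config: MotifConfig = MotifConfig(),
) -> MotifSegmentation:
    """Full motif segmentation: labels, min-duration events, turn count."""
    labels = label_frames(track, arena, config)
    events = segment_events(labels, config.min_frames)
    turns = count_turns(track, config)
    return MotifSegmentation(frame_labels=labels, events=events, turn_count=turns)


# ---------------------------------------------------------------------------
# DLC-style CSV I/O (three header rows: scorer / bodyparts / coords)

def read_dlc_csv(path, arena: ArenaConfig, fs: float = 15.0) -> PoseTrack:
    """Read a DLC-style keypoint CSV and convert coordinates to cm."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    scorer = df.columns.get_level_values(0)[0]
    coords = {}
    lik = {}
    for name in KEYPOINTS:
        xy = df[scorer][name][["x", "y"]].to_numpy(dtype=float) / arena.px_per_cm
        coords[name] = xy
        lik[name] = df[scorer][name]["likelihood"].to_numpy(dtype=float)
    return PoseTrack(
        nose=coords["nose"],
        head=coords["head"],
        body=coords["body"],
        tail=coords["tail"],
        likelihood=lik,
        fs=fs,
    )


def write_dlc_csv(track: PoseTrack, path, arena: ArenaConfig, scorer: str = "sim") -> None:
    """Write a track as a DLC-style CSV (coordinates in px via calibration)."""
    cols = pd.MultiIndex.from_product(
        [[scorer], list(KEYPOINTS), ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"],
    )
    data = np.empty((track.n_frames, len(KEYPOINTS) * 3))
    for i, name in enumerate(KEYPOINTS):
        xy = np.asarray(getattr(track, name)) * arena.px_per_cm
        data[:, 3 * i] = xy[:, 0]
        data[:, 3 * i + 1] = xy[:, 1]
        data[:, 3 * i + 2] = track.likelihood[name]
    pd.DataFrame(data, columns=cols).to_csv(path, index_label="frame")
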