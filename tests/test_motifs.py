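"""Motif deduction: likelihood filtering, velocity, labelling, segmentation."""

import numpy as np
import pytest

from hedonifeed.config import MotifConfig
from hedonifeed.motifs import (
    ArenaConfig,
    MotifEvent,
    PoseTrack,
    compute_velocity,
    count_turns,
    filter_likelihood,
    label_frames,
    read_dlc_csv,
    segment_events,
    write_dlc_csv,
)
from hedonifeed.synthetic import generate_pose_session


def make_track(body, head=None, tail=None, nose=None, lik=1.0, fs=15.0):
    body = np.asarray(body, dtype=float)
    n = len(body)
    head = body + [0.0, 3.0] if head is None else np.asarray(head, float)
    tail = body - [0.0, 3.0] if tail is None else np.asarray(tail, float)
    nose = head + [0.0, 1.0] if nose is None else np.asarray(nose, float)
    likelihood = {
        k: np.full(n, lik) if np.isscalar(lik) else np.asarray(lik[k])
        for k in ("nose", "head", "body", "tail")
    }
    return PoseTrack(
        nose=nose, head=head, body=body, tail=tail, likelihood=likelihood, fs=fs
    )


class TestLikelihoodFilter:
    def test_perfect_likelihood_keeps_all_frames(self):
        track = make_track(np.zeros((10, 2)) + 10.0)
        filter_likelihood(track)
        assert track.valid.all()

    def test_single_low_keypoint_invalidates_frame(self):
        lik = {k: np.ones(5) for k in ("nose", "head", "body", "tail")}
        lik["tail"][2] = 0.80
        track = make_track(np.zeros((5, 2)) + 10.0, lik=lik)
        filter_likelihood(track)
        assert not track.valid[2]
        assert track.valid.sum() == 4

    def test_threshold_boundary_is_inclusive(self):
        lik = {k: np.full(3, 0.85) for k in ("nose", "head", "body", "tail")}
        track = make_track(np.zeros((3, 2)) + 10.0, lik=lik)
        filter_likelihood(track)
        assert track.valid.all()


class TestVelocity:
    def test_stationary_body_zero_speed(self):
        track = make_track(np.tile([12.0, 12.0], (20, 1)))
        assert np.allclose(compute_velocity(track, ArenaConfig()), 0.0)

    @pytest.mark.parametrize(
        "step_cm,expected_speed,expected_class",
        [(0.2, 3.0, "walking"), (1.0, 15.0, "running"), (0.5, 7.5, "trotting")],
    )
    def test_constant_displacement_maps_to_class(
        self, step_cm, expected_speed, expected_class, open_field_arena
    ):
        n = 60
        body = np.column_stack([25.0 + step_cm * np.arange(n) - step_cm * n / 2,
                                np.full(n, 25.0)])
        track = make_track(body)
        speed = compute_velocity(track, open_field_arena)
        assert speed[1:] == pytest.approx(expected_speed)
        labels = label_frames(track, open_field_arena)
        assert labels[n // 2] == expected_class

    def test_smoothing_preserves_constant_velocity(self, open_field_arena):
        body = np.column_stack([10.0 + 0.2 * np.arange(90), np.full(90, 40.0)])
        track = make_track(body)
        raw = compute_velocity(track, open_field_arena, smooth_s=0.0)
        smooth = compute_velocity(track, open_field_arena, smooth_s=1.0)
        mid = slice(20, 70)
        assert np.allclose(raw[mid], smooth[mid])


class TestLabelPriority:
    def test_head_near_food_cup_is_feeding_regardless_of_motion(self, feeding_arena):
        n = 20
        head = np.tile(np.asarray(feeding_arena.cup_food_xy) + [0.0, 3.0], (n, 1))
        body = head + [0.0, 3.0]
        track = make_track(body, head=head, tail=body + [0.0, 3.0])
        labels = label_frames(track, feeding_arena)
        assert all(l == "feeding" for l in labels)

    def test_exclusion_zone_suppresses_velocity_label(self, feeding_arena):
        # head 6.5 cm from the food cup, walking speed: no label at all
        direction = np.array([1.0, 1.0]) / np.sqrt(2)
        start = np.asarray(feeding_arena.cup_food_xy) + direction * 6.5
        n = 30
        step = direction * 0.2  # 3 cm/s at 15 fps, moving away
        head = start + step * np.arange(n)[:, None]
        body = head + direction * 3.0
        track = make_track(body, head=head, tail=body + direction * 3.0)
        labels = label_frames(track, feeding_arena)
        assert labels[1] is None

    def test_rearing_when_far_from_cups(self, open_field_arena):
        n = 20
        body = np.tile([25.0, 25.0], (n, 1))
        head = body + [1.0, 0.0]  # 1 cm < 2 cm
        track = make_track(body, head=head, tail=body - [3.0, 0.0])
        labels = label_frames(track, open_field_arena)
        assert all(l == "rearing" for l in labels)

    def test_cup_tie_resolved_to_nearest(self):
        arena = ArenaConfig(
            chamber_size_cm=(25.0, 25.0),
            cup_food_xy=(10.0, 12.5),
            cup_empty_xy=(16.0, 12.5),
        )
        head = np.tile([12.0, 12.5], (10, 1))  # 2 cm from food, 4 from empty
        body = head + [0.0, 3.0]
        track = make_track(body, head=head, tail=body + [0.0, 3.0])
        labels = label_frames(track, arena)
        assert all(l == "feeding" for l in labels)


class TestSegmentation:
    def test_run_shorter_than_minimum_discarded(self):
        labels = ["feeding"] * 6 + [None] * 10
        assert segment_events(labels, min_frames=7) == []

    def test_run_at_minimum_kept(self):
        labels = ["feeding"] * 7 + [None] * 3
        events = segment_events(labels, min_frames=7)
        assert events == [MotifEvent(0, 7, "feeding")]

    def test_alternating_labels_yield_no_events(self):
        labels = ["feeding", "walking"] * 20
        assert segment_events(labels, min_frames=7) == []

    def test_invalid_frame_breaks_run(self):
        labels = ["feeding"] * 6 + [None] + ["feeding"] * 6
        assert segment_events(labels, min_frames=7) == []


class TestTurnCounting:
    def test_collinear_posture_counts_nothing(self):
        body = np.tile([25.0, 25.0], (30, 1))
        track = make_track(body, head=body + [3.0, 0.0], tail=body - [3.0, 0.0])
        assert count_turns(track) == 0

    def test_single_excursion_counts_once(self):
        n = 30
        body = np.tile([25.0, 25.0], (n, 1))
        head = body + [3.0, 0.0]
        ang = np.radians(30)
        head[10:15] = body[10:15] + 3.0 * np.array([np.cos(ang), np.sin(ang)])
        track = make_track(body, head=head, tail=body - [3.0, 0.0])
        assert count_turns(track) == 1

    def test_two_separated_excursions_count_twice(self):
        n = 40
        body = np.tile([25.0, 25.0], (n, 1))
        head = body + [3.0, 0.0]
        ang = np.radians(25)
        off = 3.0 * np.array([np.cos(ang), np.sin(ang)])
        head[5:10] = body[5:10] + off
        head[20:24] = body[20:24] + off
        track = make_track(body, head=head, tail=body - [3.0, 0.0])
        assert count_turns(track) == 2


class TestRecovery:
    SCRIPT = [
        ("feeding_jelly", 15.0),
        ("walking", 15.0),
        ("empty_cup", 15.0),
        ("stopping", 15.0),
        ("rearing", 15.0),
        ("trotting", 15.0),
        ("running", 15.0),
    ]

    def _accuracy(self, arena, noise, seed=5):
        track, truth = generate_pose_session(
            self.SCRIPT, arena, noise_cm=noise, seed=seed
        )
        labels = label_frames(track, arena)
        idx = [i for i, t in enumerate(truth) if t is not None]
        return float(np.mean([labels[i] == truth[i] for i in idx]))

    def test_noise_free_recovery_is_exact(self, open_field_arena):
        assert self._accuracy(open_field_arena, 0.0) == 1.0

    def test_noisy_recovery_above_95_percent(self, open_field_arena):
        assert self._accuracy(open_field_arena, 0.3) >= 0.95


class TestDlcRoundtrip:
    def test_write_then_read_recovers_track(self, tmp_path, open_field_arena):
        track, _ = generate_pose_session(
            [("walking", 5.0)], open_field_arena, noise_cm=0.1, seed=2
        )
        path = tmp_path / "pose.csv"
        write_dlc_csv(track, path, open_field_arena)
        back = read_dlc_csv(path, open_field_arena)
        assert np.allclose(back.body, track.body)
        assert np.allclose(back.likelihood["head"], track.likelihood["head"])
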