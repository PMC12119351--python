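"""Generator contracts: determinism, support, statistical calibration."""

import numpy as np
import pytest

from hedonifeed.motifs import compute_velocity
from hedonifeed.synthetic import (
    FishSimParams,
    PhotometrySimParams,
    SpikeSimParams,
    generate_fish_dataset,
    generate_photometry_trace,
    generate_piezo_train,
    generate_pose_session,
    generate_spike_session,
    transient_auc_truth,
)


class TestSpikeGenerator:
    def test_zero_rate_empty_train(self):
        p = SpikeSimParams(baseline_rate=0.0, light_response_prob=0.0)
        spikes, evoked = generate_spike_session(p, seed=0)
        assert spikes.size == 0

    def test_determinism(self):
        p = SpikeSimParams(baseline_rate=5.0, light_response_prob=0.5)
        pulses = np.arange(100) / 2.0
        a = generate_spike_session(p, pulses, seed=42)
        b = generate_spike_session(p, pulses, seed=42)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_poisson_count_within_three_sigma(self):
        p = SpikeSimParams(baseline_rate=5.0, duration_s=600.0)
        spikes, _ = generate_spike_session(p, seed=77)
        assert abs(spikes.size - 3000) < 3 * np.sqrt(3000)

    def test_event_gain_raises_rate_in_window(self):
        onsets = 10.0 + 20.0 * np.arange(25)
        p = SpikeSimParams(
            baseline_rate=5.0, event_gain=3.0, duration_s=onsets[-1] + 10
        )
        spikes, _ = generate_spike_session(
            p, events=[(o, "feeding") for o in onsets], seed=5
        )
        in_ev = sum(
            np.sum((spikes >= o) & (spikes < o + 3.0)) for o in onsets
        ) / (3.0 * len(onsets))
        assert in_ev == pytest.approx(15.0, rel=0.15)

    def test_spikes_stay_in_session(self):
        p = SpikeSimParams(baseline_rate=20.0, duration_s=30.0)
        spikes, _ = generate_spike_session(p, seed=9)
        assert spikes.min() >= 0
        assert spikes.max() <= 30.0

    def test_refractory_enforced(self):
        p = SpikeSimParams(baseline_rate=200.0, duration_s=20.0, refractory_ms=2.0)
        spikes, _ = generate_spike_session(p, seed=3)
        assert np.diff(spikes).min() >= 0.002 - 1e-12

    def test_evoked_mask_marks_short_latency_spikes(self):
        pulses = np.arange(100) / 2.0
        p = SpikeSimParams(
            baseline_rate=0.0, light_response_prob=1.0, duration_s=55.0
        )
        spikes, evoked = generate_spike_session(p, pulses, seed=1)
        assert evoked.all()
        lats = spikes - pulses[np.searchsorted(pulses, spikes) - 1]
        assert np.all(lats > 0)
        assert np.percentile(lats * 1000, 95) < 6.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SpikeSimParams(baseline_rate=-1.0)
        with pytest.raises(ValueError):
            SpikeSimParams(light_response_prob=1.5)
        with pytest.raises(ValueError):
            SpikeSimParams(duration_s=float("nan"))


class TestPoseGenerator:
    def test_stopping_script_zero_velocity(self, open_field_arena):
        track, _ = generate_pose_session(
            [("stopping", 10.0)], open_field_arena, noise_cm=0.0, seed=0
        )
        speed = compute_velocity(track, open_field_arena)
        assert np.allclose(speed, 0.0)

    def test_running_script_fast_displacement(self, open_field_arena):
        track, _ = generate_pose_session(
            [("running", 2.0)], open_field_arena, noise_cm=0.0, seed=0
        )
        disp = np.linalg.norm(np.diff(track.body, axis=0), axis=1)
        assert np.all(disp > 10.0 / track.fs)

    @pytest.mark.parametrize("dropout,check", [(0.0, "all_high"), (1.0, "all_low")])
    def test_dropout_boundaries(self, dropout, check, open_field_arena):
        track, _ = generate_pose_session(
            [("stopping", 5.0)],
            open_field_arena,
            likelihood_dropout=dropout,
            seed=6,
        )
        for k in ("nose", "head", "body", "tail"):
            if check == "all_high":
                assert np.all(track.likelihood[k] >= 0.85)
            else:
                assert np.all(track.likelihood[k] < 0.85)

    def test_determinism(self, open_field_arena):
        script = [("feeding_jelly", 5.0), ("walking", 5.0)]
        a, ta = generate_pose_session(script, open_field_arena, noise_cm=0.2, seed=11)
        b, tb = generate_pose_session(script, open_field_arena, noise_cm=0.2, seed=11)
        assert np.array_equal(a.body, b.body)
        assert ta == tb

    def test_track_stays_in_arena(self, open_field_arena):
        script = [("running", 20.0), ("feeding_jelly", 5.0), ("rearing", 5.0)]
        track, _ = generate_pose_session(script, open_field_arena, seed=2)
        w, h = open_field_arena.chamber_size_cm
        assert track.body[:, 0].min() >= 0 and track.body[:, 0].max() <= w
        assert track.body[:, 1].min() >= 0 and track.body[:, 1].max() <= h

    def test_unknown_state_rejected(self, open_field_arena):
        with pytest.raises(ValueError):
            generate_pose_session([("flying", 5.0)], open_field_arena)


class TestPiezoGenerator:
    def test_empty_bouts_empty_train(self):
        assert generate_piezo_train([], seed=0).size == 0

    def test_support_constraint(self):
        times = generate_piezo_train([(10.0, 20.0)], intra_rate=2.0, seed=1)
        assert times.min() >= 10.0
        assert times.max() <= 20.0
        assert 10.0 in times and 20.0 in times

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError):
            generate_piezo_train([(0.0, 5.0), (4.0, 8.0)])

    def test_determinism(self):
        a = generate_piezo_train([(0.0, 5.0), (20.0, 30.0)], seed=7)
        b = generate_piezo_train([(0.0, 5.0), (20.0, 30.0)], seed=7)
        assert np.array_equal(a, b)


class TestPhotometryGenerator:
    def test_silent_trace_zero_outside_artifact(self):
        p = PhotometrySimParams(
            noise_sd=0.0, transient_amp=0.0, bleach_amp=0.0, artifact_amp=-0.05
        )
        trace, _ = generate_photometry_trace(p, [20.0], seed=0)
        outside = (trace.t_s < 20.0) | (trace.t_s >= 21.0)
        assert np.allclose(trace.f[outside], 0.0)

    def test_transient_peak_at_delay(self):
        p = PhotometrySimParams(
            noise_sd=0.0, artifact_amp=0.0, bleach_amp=0.0, transient_amp=0.07
        )
        trace, _ = generate_photometry_trace(p, [20.0], seed=0)
        i_peak = np.argmax(trace.f)
        assert trace.t_s[i_peak] == pytest.approx(20.0 + p.transient_delay_s)
        assert trace.f[i_peak] == pytest.approx(0.07)

    def test_analytic_transient_auc(self):
        p = PhotometrySimParams(transient_amp=0.05, transient_tau_s=1.5)
        assert transient_auc_truth(p, 2 * 1.5) == pytest.approx(
            0.05 * 1.5 * (1 - np.exp(-2))
        )

    def test_determinism(self):
        p = PhotometrySimParams(noise_sd=0.01)
        a, _ = generate_photometry_trace(p, [20.0], seed=5)
        b, _ = generate_photometry_trace(p, [20.0], seed=5)
        assert np.array_equal(a.f, b.f)


class TestFishGenerator:
    def test_zero_pos_fraction_identical_statistics(self):
        p = FishSimParams(pos_fraction=0.0)
        cells, labels = generate_fish_dataset(p, 50, 50, seed=3)
        means = np.array([c.mean_intensity for c in cells])
        lab = np.array(labels)
        assert abs(means[lab].mean() - means[~lab].mean()) < 1.5

    def test_determinism(self):
        p = FishSimParams()
        a, _ = generate_fish_dataset(p, 10, 10, seed=9)
        b, _ = generate_fish_dataset(p, 10, 10, seed=9)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.pixel_intensities, cb.pixel_intensities)

    def test_intensities_clipped_to_range(self):
        p = FishSimParams(null_mean=240.0, null_sd=20.0, pos_shift=60.0)
        cells, _ = generate_fish_dataset(p, 5, 5, seed=1)
        for c in cells:
            assert c.pixel_intensities.min() >= 0
            assert c.pixel_intensities.max() <= 255.0

    def test_pixel_floor_enforced(self):
        with pytest.raises(ValueError):
            FishSimParams(pixels_per_cell=10)
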