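"""Track classification, segmentation, velocities, and summaries."""

import numpy as np
import pytest

from bioidpipe.motility import (
    DIFFUSIVE,
    NON_MOTILE,
    PROCESSIVE,
    EventSegment,
    Track,
    classify_event,
    classify_track,
    event_velocity,
    segment_events,
    summarize_motility,
)
from bioidpipe.simulate import TrackSimConfig, generate_tracks


def track(positions, dt=0.5, label=None):
    positions = np.asarray(positions, dtype=float)
    return Track(
        track_id="t", times=np.arange(positions.size) * dt, positions=positions,
        label=label,
    )


class TestClassifyEvent:
    def test_monotone_long_drift_is_processive(self):
        assert classify_event(np.linspace(0, 2000, 40)) == PROCESSIVE

    def test_bidirectional_excursions_are_diffusive(self):
        pos = np.concatenate([np.linspace(0, 800, 10), np.linspace(800, 0, 10)])
        assert classify_event(pos) == DIFFUSIVE

    def test_small_oscillation_is_non_motile(self):
        pos = 200 * np.sin(np.linspace(0, 6 * np.pi, 50))
        assert classify_event(pos) == NON_MOTILE

    def test_600nm_boundary_is_exclusive(self):
        # exactly 600 nm in each direction is NOT greater than 600
        pos = np.concatenate([np.linspace(0, 600, 10), np.linspace(600, 0, 10)])
        assert classify_event(pos) != DIFFUSIVE
        # net displacement of exactly 600 is not processive either
        assert classify_event(np.linspace(0, 600, 10)) == NON_MOTILE
        assert classify_event(np.linspace(0, 600.1, 10)) == PROCESSIVE

    def test_one_way_long_run_never_diffusive(self):
        assert classify_event(np.linspace(0, 10_000, 100)) == PROCESSIVE

    def test_offset_and_sign_invariance(self, rng):
        for _ in range(10):
            pos = np.cumsum(rng.normal(0, 300, size=60))
            base = classify_event(pos)
            assert classify_event(pos + 5000) == base
            flipped = classify_event(-pos)
            assert flipped == base  # classes are direction-symmetric

    def test_reversal_threshold_configurable(self):
        pos = np.concatenate([np.linspace(0, 500, 10), np.linspace(500, 0, 10)])
        assert classify_event(pos, reversal_nm=600) == NON_MOTILE
        assert classify_event(pos, reversal_nm=400) == DIFFUSIVE


class TestSegmentation:
    def test_static_then_processive_gives_two_events(self):
        pos = np.concatenate([np.zeros(40), np.arange(40) * 150.0])
        segs = segment_events(track(pos))
        assert [s.event_class for s in segs] == [NON_MOTILE, PROCESSIVE]

    def test_pure_processive_track_is_one_event(self):
        segs = segment_events(track(np.arange(50) * 150.0))
        assert len(segs) == 1
        assert segs[0].event_class == PROCESSIVE

    def test_segments_cover_track_in_order(self):
        pos = np.concatenate(
            [np.zeros(30), np.arange(30) * 200.0, np.full(30, 5800.0)]
        )
        segs = segment_events(track(pos))
        assert segs[0].start == 0
        assert segs[-1].stop == len(pos) - 1
        for a, b in zip(segs[:-1], segs[1:]):
            assert b.start == a.stop + 1  # exact partition of the frames

    def test_time_reversed_track_has_mirrored_boundaries(self):
        pos = np.concatenate([np.zeros(35), np.arange(45) * 180.0])
        tr = track(pos)
        rev = Track(track_id="r", times=tr.times, positions=pos[::-1].copy())
        n = pos.size - 1
        fwd = [(s.start, s.stop) for s in segment_events(tr)]
        bwd = [(n - s.stop, n - s.start) for s in segment_events(rev)]
        assert fwd == sorted(bwd)


class TestVelocity:
    def seg(self, positions, dt=0.5, cls=PROCESSIVE):
        positions = np.asarray(positions, dtype=float)
        return EventSegment(
            track_id="t", start=0, stop=positions.size - 1,
            times=np.arange(positions.size) * dt, positions=positions,
            event_class=cls,
        )

    def test_exact_line_velocity(self):
        # 100 nm per 0.5 s frame over 20 frames -> 200 nm/s
        seg = self.seg(np.arange(21) * 100.0)
        assert event_velocity(seg) == pytest.approx(200.0)

    def test_five_frame_segment_excluded(self):
        seg = self.seg(np.arange(6) * 400.0)  # 5 frame intervals
        assert seg.n_frames == 5
        assert event_velocity(seg) is None
        assert event_velocity(self.seg(np.arange(7) * 400.0)) is not None

    def test_non_processive_excluded(self):
        seg = self.seg(np.arange(21) * 100.0, cls=DIFFUSIVE)
        assert event_velocity(seg) is None

    def test_endpoint_mode_matches_slope_on_exact_line(self):
        seg = self.seg(np.arange(21) * 100.0)
        assert event_velocity(seg, mode="endpoint") == pytest.approx(
            event_velocity(seg, mode="slope")
        )

    def test_noisy_slope_recovery_within_3se(self, rng):
        """Least-squares slope recovers the generating velocity: over 200
        noisy lines the mean estimate sits within 3 standard errors."""
        true_v, noise_sd, n_frames, dt = 150.0, 30.0, 50, 0.5
        t = np.arange(n_frames + 1) * dt
        estimates = []
        for _ in range(200):
            pos = true_v * t + rng.normal(0, noise_sd, size=t.size)
            estimates.append(event_velocity(self.seg(pos)))
        # regression theory: var(slope) = sigma^2 / sum((t - tbar)^2)
        se_single = noise_sd / np.sqrt(np.sum((t - t.mean()) ** 2))
        se_mean = se_single / np.sqrt(200)
        assert abs(np.mean(estimates) - true_v) < 3 * se_mean

    def test_sign_flip_negates_velocity(self):
        seg_up = self.seg(np.arange(21) * 100.0)
        seg_down = self.seg(-np.arange(21) * 100.0)
        assert event_velocity(seg_down) == pytest.approx(-event_velocity(seg_up))


class TestSummarize:
    def test_constant_velocity_set_has_zero_sd(self):
        tracks = [track(np.arange(30) * 200.0, label=PROCESSIVE) for _ in range(5)]
        summary = summarize_motility(tracks)
        assert summary.mean_velocity == pytest.approx(400.0)
        assert summary.sd_velocity == pytest.approx(0.0, abs=1e-9)
        assert summary.fractions[PROCESSIVE] == 1.0

    def test_empty_velocity_pool_flagged(self):
        tracks = [track(np.zeros(20)) for _ in range(3)]
        summary = summarize_motility(tracks)
        assert summary.n_velocity == 0
        assert np.isnan(summary.mean_velocity)
        assert summary.fractions[NON_MOTILE] == 1.0

    def test_fractions_sum_to_one(self):
        tracks = generate_tracks(TrackSimConfig(n_tracks=60, seed=5))
        summary = summarize_motility(tracks)
        assert sum(summary.fractions.values()) == pytest.approx(1.0)

    def test_mixture_fractions_recovered_within_3se(self):
        """Class fractions over 1000 single-behavior tracks match the
        generating mixture to within 3 binomial standard errors, both for
        whole-track classification and for the full segment-and-summarize
        path (which may split the odd track, hence the small slack)."""
        mix = (0.5, 0.3, 0.2)
        tracks = generate_tracks(
            TrackSimConfig(n_tracks=1000, class_mixture=mix, seed=7)
        )
        counts = {PROCESSIVE: 0, DIFFUSIVE: 0, NON_MOTILE: 0}
        for tr in tracks:
            counts[classify_track(tr)] += 1
        n = len(tracks)
        summary = summarize_motility(tracks)
        for p_true, cls in zip(mix, (PROCESSIVE, DIFFUSIVE, NON_MOTILE)):
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(counts[cls] / n - p_true) < 3 * se + 0.02
            assert abs(summary.fractions[cls] - p_true) < 3 * se + 0.02


class TestGeneratedRecovery:
    def test_class_recovery_at_least_95_percent(self):
        tracks = generate_tracks(TrackSimConfig(n_tracks=500, seed=13))
        agree = np.mean([classify_track(t) == t.label for t in tracks])
        assert agree >= 0.95
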