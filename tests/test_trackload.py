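"""Position morphing, segmentation, wavelet band power, tercile load maps
and behavioral summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from driveload.datatypes import ContinuousRecording, MONTAGE_32, LoadMap
from driveload import trackload as tl

FS = 500.0


class TestPosition:
    def test_constant_velocity_closed_form(self):
        n = 20000
        v = np.full(n, 90.0)  # 25 m/s
        truth = 25.0 * np.arange(n) / FS
        triggers = [(2000, truth[2000]), (10000, truth[10000]),
                    (18000, truth[18000])]
        dist = tl.reconstruct_position(v, triggers, FS)
        np.testing.assert_allclose(dist, truth, atol=1e-8)

    def test_velocity_bias_corrected_at_triggers(self):
        n = 20000
        truth = 25.0 * np.arange(n) / FS
        v = np.full(n, 90.0) * 1.05  # +5% multiplicative bias
        triggers = [(1000, truth[1000]), (8000, truth[8000]),
                    (15000, truth[15000]), (19000, truth[19000])]
        dist = tl.reconstruct_position(v, triggers, FS)
        for s, d in triggers:
            assert abs(dist[s] - d) < 1e-9
        # multiplicative bias is removed exactly by per-interval rescaling
        mid = slice(8000, 15000)
        interval_len = truth[15000] - truth[8000]
        assert np.abs(dist[mid] - truth[mid]).max() < 0.05 * interval_len

    def test_morphing_idempotent_on_consistent_velocity(self, rng):
        n = 10000
        v = 80.0 + 10.0 * np.sin(np.arange(n) / 1000.0) + rng.normal(0, 1, n)
        raw = np.concatenate([[0.0], np.cumsum(
            0.5 * (v[1:] + v[:-1]) / 3.6)]) / FS
        triggers = [(i, raw[i]) for i in (500, 4000, 9500)]
        dist = tl.reconstruct_position(v, triggers, FS)
        inner = slice(500, 9501)
        assert np.abs(dist[inner] - raw[inner]).max() < 1e-9

    def test_non_monotone_triggers_rejected(self):
        with pytest.raises(ValueError):
            tl.reconstruct_position(np.full(100, 90.0),
                                    [(10, 100.0), (50, 50.0)], FS)


class TestSegmentation:
    def test_50km_gives_5000_segments(self):
        dist = np.linspace(0, 50_000, 200_000)
        segs = tl.segment_track(dist, max_distance=50_000.0)
        assert len(segs) == 5000

    def test_ten_meter_drive_one_segment(self):
        segs = tl.segment_track(np.linspace(0, 10, 500), max_distance=10.0)
        assert len(segs) == 1

    def test_short_track_warns_empty(self):
        with pytest.warns(UserWarning):
            assert tl.segment_track(np.linspace(0, 5, 100),
                                    max_distance=5.0) == []

    def test_boundaries_match_brute_force(self, rng):
        n = 30000
        v = np.clip(60 + 40 * np.sin(np.arange(n) / 2500.0)
                    + rng.normal(0, 3, n), 5, None)
        dist = np.concatenate([[0], np.cumsum(v[1:] / 3.6)]) / FS
        segs = tl.segment_track(dist, seg_len=10.0)
        # brute force: assign every sample to its bin, compare spans
        bins = (dist // 10.0).astype(int)
        for seg in segs:
            members = np.flatnonzero(bins == seg.index)
            if len(members):
                assert seg.sample_span == (members[0], members[-1] + 1)
            else:
                assert seg.n_samples == 0
        covered = sum(s.n_samples for s in segs)
        assert covered == np.count_nonzero(dist < len(segs) * 10.0)


class TestWavelet:
    def test_pure_tone_peaks_at_matching_bin(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        p = tl.cwt_power(x, FS)
        freqs, _ = tl.wavelet_grid()
        mid = p[0, :, int(10 * FS):int(20 * FS)].mean(axis=1)
        assert freqs[np.argmax(mid)] == 10.0

    def test_zero_signal_zero_power(self):
        p = tl.cwt_power(np.zeros(int(10 * FS)), FS)
        assert np.all(p == 0)

    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.normal(size=int(10 * FS))
        p1 = tl.cwt_power(x, FS)
        p2 = tl.cwt_power(2 * x, FS)
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-6)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="short"):
            tl.cwt_power(np.zeros(100), FS)

    def test_freq_subset_identical_to_full_grid(self, rng):
        x = rng.normal(size=int(5 * FS))
        full = tl.cwt_power(x, FS)
        sub = tl.cwt_power(x, FS, freq_indices=np.array([2, 6, 10]))
        np.testing.assert_allclose(sub, full[:, [2, 6, 10]], rtol=1e-12)


class TestZScore:
    def test_mean_zero_sd_one(self, rng):
        p = rng.exponential(size=(3, 5, 1000))
        z = tl.zscore_trace(p)
        assert np.abs(z.mean(axis=-1)).max() < 1e-10
        assert np.abs(z.std(axis=-1) - 1).max() < 1e-10

    def test_affine_invariance(self, rng):
        p = rng.exponential(size=(2, 3, 500))
        np.testing.assert_allclose(tl.zscore_trace(3.7 * p + 11.0),
                                   tl.zscore_trace(p), atol=1e-9)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            tl.zscore_trace(np.ones((1, 2, 100)))


class TestSegmentAverageSmooth:
    def _segments(self, n_seg, samples_per_seg=50):
        from driveload.datatypes import TrackSegment

        return [TrackSegment(i, (i * 10.0, (i + 1) * 10.0),
                             (i * samples_per_seg, (i + 1) * samples_per_seg))
                for i in range(n_seg)]

    def test_constant_preserved(self):
        segs = self._segments(30)
        z = np.full((1, 1, 1500), 3.3)
        out = tl.segment_average_and_smooth(z, segs)
        np.testing.assert_allclose(out, 3.3)

    def test_impulse_spreads_over_eleven_segments(self):
        segs = self._segments(40)
        z = np.zeros((1, 1, 2000))
        z[0, 0, 20 * 50:21 * 50] = 1.0  # one segment's worth
        out = tl.segment_average_and_smooth(z, segs)[0, 0]
        interior = out[15:26]
        np.testing.assert_allclose(interior, 1 / 11, atol=1e-12)
        assert out[10] == 0.0 and out[30] == 0.0

    def test_edge_window_shrinks_symmetrically(self):
        segs = self._segments(20)
        z = np.zeros((1, 1, 1000))
        z[0, 0, :50] = 1.0  # impulse in segment 0
        out = tl.segment_average_and_smooth(z, segs)[0, 0]
        # pandas centered rolling with min_periods=1: segment 0's window
        # covers segments 0..5 (6 values)
        assert out[0] == pytest.approx(1 / 6)

    def test_empty_segment_becomes_nan(self):
        from driveload.datatypes import TrackSegment

        segs = [TrackSegment(0, (0, 10), (0, 50)),
                TrackSegment(1, (10, 20), (50, 50)),
                TrackSegment(2, (20, 30), (50, 100))]
        out = tl.segment_average_and_smooth(np.ones((1, 1, 100)), segs,
                                            smooth_segments=0)
        assert np.isnan(out[0, 0, 1])
        assert out[0, 0, 0] == 1.0


class TestBandClusters:
    def test_cluster_mean_matches_brute_force(self, rng):
        freqs, _ = tl.wavelet_grid()
        vals = rng.normal(size=(32, 29, 17))
        theta, alpha = tl.band_cluster_power(vals, freqs, MONTAGE_32)
        fr = [MONTAGE_32.index(c) for c in tl.FRONTAL_THETA_CLUSTER]
        tbins = [i for i, f in enumerate(freqs) if 4 <= f <= 7]
        brute = vals[fr][:, tbins].mean(axis=(0, 1))
        np.testing.assert_allclose(theta, brute, atol=1e-12)

    def test_uniform_power_symmetric(self):
        freqs, _ = tl.wavelet_grid()
        vals = np.ones((32, 29, 5)) * 2.5
        theta, alpha = tl.band_cluster_power(vals, freqs, MONTAGE_32)
        np.testing.assert_allclose(theta, alpha)

    def test_missing_cluster_channel(self, rng):
        freqs, _ = tl.wavelet_grid()
        with pytest.raises(KeyError, match="FC1"):
            tl.band_cluster_power(rng.normal(size=(3, 29, 5)), freqs,
                                  ["F3", "Fz", "F4"])


class TestTaskLoad:
    def test_monotone_scores_split_in_order(self):
        scores = np.linspace(10, -10, 3000)[None, :]  # strictly decreasing
        lm = tl.assign_task_load(scores)
        assert np.all(lm.labels[:1000] == "low")
        assert np.all(lm.labels[1000:2000] == "medium")
        assert np.all(lm.labels[2000:] == "high")

    def test_counts_on_5000_segments(self, rng):
        lm = tl.assign_task_load(rng.normal(size=(4, 5000)))
        counts = pd.Series(lm.labels).value_counts()
        assert set(counts.values) <= {1666, 1667}

    @given(st.integers(0, 2 ** 31 - 1), st.integers(10, 300))
    @settings(max_examples=25, deadline=None)
    def test_partition_counts_and_determinism(self, seed, n):
        values = np.random.default_rng(seed).normal(size=n)
        bins = tl.tercile_partition(values)
        _, counts = np.unique(bins, return_counts=True)
        assert counts.max() - counts.min() <= 1
        assert np.array_equal(bins, tl.tercile_partition(values))

    def test_ties_broken_by_segment_index(self):
        bins = tl.tercile_partition(np.zeros(9))
        np.testing.assert_array_equal(bins, [0, 0, 0, 1, 1, 1, 2, 2, 2])

    def test_nan_segments_unassigned(self):
        scores = np.array([[1.0, np.nan, -1.0, 0.0, 2.0, -2.0]])
        lm = tl.assign_task_load(scores)
        assert lm.labels[1] == "unassigned"
        assert set(lm.labels) >= {"low", "medium", "high"}


class TestPipelineEquivalence:
    def test_lean_scores_equal_composed_operations(self, rng):
        n = int(30 * FS)
        data = rng.normal(size=(32, n))
        rec = ContinuousRecording(data, FS, MONTAGE_32)
        dist = np.linspace(0, 140.0, n)
        segs = tl.segment_track(dist, max_distance=140.0)
        theta, alpha = tl.segment_band_scores(rec, segs, bands_only=False)
        power = tl.cwt_power(data, FS)
        z = tl.zscore_trace(power)
        seg_vals = tl.segment_average_and_smooth(z, segs)
        freqs, _ = tl.wavelet_grid()
        theta2, alpha2 = tl.band_cluster_power(seg_vals, freqs, MONTAGE_32)
        np.testing.assert_allclose(theta, theta2, atol=1e-10)
        np.testing.assert_allclose(alpha, alpha2, atol=1e-10)

    def test_bands_only_matches_full_grid(self, rng):
        n = int(20 * FS)
        rec = ContinuousRecording(rng.normal(size=(32, n)), FS, MONTAGE_32)
        segs = tl.segment_track(np.linspace(0, 90.0, n), max_distance=90.0)
        a = tl.segment_band_scores(rec, segs, bands_only=True)
        b = tl.segment_band_scores(rec, segs, bands_only=False)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestBehavior:
    def _setup(self, rng, velocity=90.0):
        n = int(60 * FS)
        rec = ContinuousRecording(
            rng.normal(size=(32, n)), FS, MONTAGE_32,
            telemetry={"velocity": np.full(n, velocity),
                       "steering": rng.normal(0, 1, n)})
        dist = np.linspace(0, 1500.0, n)
        segs = tl.segment_track(dist, max_distance=1500.0)
        labels = np.array(["low", "medium", "high"], dtype=object)[
            np.arange(len(segs)) % 3]
        lm = LoadMap(score=np.zeros(len(segs)), cutpoints=(0, 0),
                     labels=labels)
        return rec, segs, lm

    def test_constant_velocity_everywhere(self, rng):
        rec, segs, lm = self._setup(rng)
        beh = tl.summarize_behavior(segs, rec, [], lm)
        np.testing.assert_allclose(beh["velocity"], 90.0, atol=1e-9)

    def test_no_events_zero_rates(self, rng):
        rec, segs, lm = self._setup(rng)
        beh = tl.summarize_behavior(segs, rec, [], lm)
        assert (beh[["blink_per_min", "outward_per_min",
                     "inward_per_min"]] == 0).all().all()

    def test_missing_telemetry_rejected(self, rng):
        rec, segs, lm = self._setup(rng)
        rec.telemetry = None
        with pytest.raises(ValueError):
            tl.summarize_behavior(segs, rec, [], lm)
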