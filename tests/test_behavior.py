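"""Face-up detection, event labeling and design-matrix construction."""

import numpy as np
import pytest

from hypercoh import behavior
from hypercoh.behavior import (build_design, detect_face_up, label_events,
                               zscore_pitch)
from hypercoh.errors import AlignmentError, DegenerateInputError, ParameterError
from hypercoh.io import PoseSeries


def _pose(pitch, fs=29.97, valid=None):
    return PoseSeries(participant_id="p", fs=fs, pitch=pitch, valid=valid)


class TestZscore:
    def test_affine_invariance(self, rng):
        pitch = rng.standard_normal(3000)
        z1 = zscore_pitch(_pose(pitch))
        z2 = zscore_pitch(_pose(3.5 * pitch + 0.7))
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_normalization(self, rng):
        z = zscore_pitch(_pose(rng.standard_normal(10_000) * 0.05 + 0.3))
        assert abs(z.mean()) < 0.02 and abs(z.std() - 1.0) < 0.02

    def test_constant_pitch_rejected(self):
        with pytest.raises(DegenerateInputError):
            zscore_pitch(_pose(np.full(3000, 0.2)))

    def test_invalid_samples_excluded_from_moments(self, rng):
        pitch = rng.standard_normal(3000)
        spoiled = pitch.copy()
        spoiled[:100] = 1e6  # huge values on invalid frames must not leak in
        valid = np.ones(3000, dtype=bool)
        valid[:100] = False
        z = zscore_pitch(_pose(spoiled, valid=valid))
        ref = (pitch[100:] - pitch[100:].mean()) / pitch[100:].std()
        np.testing.assert_allclose(z[100:], ref, atol=1e-10)
        assert np.isnan(z[:100]).all()

    def test_too_little_valid_data_rejected(self, rng):
        with pytest.raises(ParameterError):
            zscore_pitch(_pose(rng.standard_normal(100)))


class TestDetectFaceUp:
    def test_gaussian_tail_fraction(self):
        z = np.random.default_rng(0).standard_normal(1_000_000)
        frac = detect_face_up(z, threshold=2.0).mean()
        assert frac == pytest.approx(0.02275, abs=0.001)

    def test_zero_threshold_median_split(self):
        z = np.random.default_rng(0).standard_normal(100_000)
        assert detect_face_up(z, threshold=0.0).mean() == pytest.approx(0.5, abs=0.01)

    def test_nan_never_up(self):
        z = np.array([np.nan, 3.0, 1.0])
        assert detect_face_up(z).tolist() == [False, True, False]

    def test_negative_direction(self):
        z = np.array([-3.0, 3.0])
        assert detect_face_up(z, positive=False).tolist() == [True, False]


class TestLabelEvents:
    fs = 10.0

    def test_identical_tracks_all_both(self):
        up = np.zeros(200, dtype=bool)
        up[50:100] = True
        tracks = label_events(up, up, self.fs)
        np.testing.assert_array_equal(tracks.both_up, up)
        assert not tracks.self_up_a.any() and not tracks.self_up_b.any()

    def test_disjoint_tracks_partition(self):
        up_a = np.zeros(300, dtype=bool)
        up_b = np.zeros(300, dtype=bool)
        up_a[50:100] = True
        up_b[150:200] = True
        tracks = label_events(up_a, up_b, self.fs)
        assert not tracks.both_up.any()
        np.testing.assert_array_equal(tracks.self_up_a, up_a)
        np.testing.assert_array_equal(tracks.self_up_b, up_b)

    def test_mutual_exclusivity_and_completeness(self, rng):
        up_a = rng.random(2000) > 0.7
        up_b = rng.random(2000) > 0.7
        tracks = label_events(up_a, up_b, self.fs, min_duration_s=0, merge_gap_s=0)
        overlap = (tracks.both_up & tracks.self_up_a) | \
                  (tracks.both_up & tracks.self_up_b) | \
                  (tracks.self_up_a & tracks.self_up_b)
        assert not overlap.any()
        union = tracks.both_up | tracks.self_up_a | tracks.self_up_b
        np.testing.assert_array_equal(union, up_a | up_b)

    def test_swap_symmetry(self, rng):
        up_a = rng.random(1000) > 0.8
        up_b = rng.random(1000) > 0.8
        fwd = label_events(up_a, up_b, self.fs)
        rev = label_events(up_b, up_a, self.fs)
        np.testing.assert_array_equal(fwd.self_up_a, rev.self_up_b)
        np.testing.assert_array_equal(fwd.self_up_b, rev.self_up_a)
        np.testing.assert_array_equal(fwd.both_up, rev.both_up)

    def test_short_run_dropped(self):
        up = np.zeros(100, dtype=bool)
        up[10:13] = True  # 0.3 s at 10 Hz
        tracks = label_events(up, np.zeros(100, dtype=bool), self.fs,
                              min_duration_s=0.5, merge_gap_s=0)
        assert not tracks.self_up_a.any()
        assert tracks.events.empty

    def test_short_gap_bridged(self):
        up = np.zeros(100, dtype=bool)
        up[10:20] = True
        up[21:30] = True  # 0.1 s dip
        tracks = label_events(up, np.zeros(100, dtype=bool), self.fs,
                              min_duration_s=0, merge_gap_s=0.2)
        assert tracks.self_up_a[10:30].all()
        assert len(tracks.events) == 1

    def test_rate_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            label_events(np.zeros(10, dtype=bool), np.zeros(11, dtype=bool), self.fs)


class TestBuildDesign:
    pose_fs = 29.97

    def _tracks(self, n, both=(), self_a=(), self_b=()):
        def raster(epochs):
            return behavior.binary_track_from_epochs(epochs, self.pose_fs, n)

        up_a = raster(both) | raster(self_a)
        up_b = raster(both) | raster(self_b)
        return label_events(up_a, up_b, self.pose_fs, min_duration_s=0,
                            merge_gap_s=0)

    def test_all_zero_tracks(self):
        tracks = self._tracks(3000)
        x, valid = build_design(tracks, 1000, target_fs=10.0, delay_s=5.0)
        assert (x["const"] == 1.0).all()
        assert x[["both_up", "self_up", "other_up"]].to_numpy().sum() == 0
        assert valid.sum() == len(x)

    def test_single_event_shifted_support(self):
        """A 3 s both-up event at t=100 with a 5 s delay appears in the
        regressor at 105-108 s on the 10 Hz analysis grid."""
        n_pose = int(600 * self.pose_fs)
        tracks = self._tracks(n_pose, both=[(100.0, 103.0)])
        x, valid = build_design(tracks, 6000, target_fs=10.0, delay_s=5.0)
        times = (np.arange(6000) / 10.0)[valid]
        support = times[x["both_up"].to_numpy() > 0]
        assert support.min() == pytest.approx(105.0, abs=0.1)
        assert support.max() == pytest.approx(108.0, abs=0.1)
        assert 28 <= support.size <= 32

    def test_identity_configuration_round_trip(self, rng):
        up = rng.random(500) > 0.8
        tracks = label_events(up, up, self.pose_fs, min_duration_s=0, merge_gap_s=0)
        x, valid = build_design(tracks, 500, target_fs=self.pose_fs, delay_s=0.0)
        assert valid.all()
        np.testing.assert_array_equal(x["both_up"].to_numpy().astype(bool),
                                      tracks.both_up)

    def test_perspective_swaps_self_and_other(self, rng):
        up_a = rng.random(1000) > 0.8
        up_b = rng.random(1000) > 0.8
        tracks = label_events(up_a, up_b, self.pose_fs, min_duration_s=0,
                              merge_gap_s=0)
        xa, _ = build_design(tracks, 300, target_fs=10.0, delay_s=0.0,
                             perspective="A")
        xb, _ = build_design(tracks, 300, target_fs=10.0, delay_s=0.0,
                             perspective="B")
        np.testing.assert_array_equal(xa["self_up"], xb["other_up"])
        np.testing.assert_array_equal(xa["other_up"], xb["self_up"])
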