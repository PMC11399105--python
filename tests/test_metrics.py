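"""Track-comparison metrics against brute-force oracles and the printed
toy conversions."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emitrack.core import TrackSet
from emitrack.metrics import (
    dual_view_tracking_error,
    gated_track_distance,
    localization_resolution,
    pair_track_sets,
    tracking_error,
)

PIXEL = 133.0
GATE_5PX = 5 * PIXEL  # 665 nm


def brute_pairing_total(ts1: TrackSet, ts2: TrackSet, eps: float) -> float:
    """Exhaustive minimum over all one-to-one pairings, unmatched tracks
    costing eps*N each; the independent oracle for the assignment solver."""
    m1, m2, N = ts1.n_tracks, ts2.n_tracks, ts1.n_frames
    cost = np.array([[gated_track_distance(TrackSet(ts1.positions[i : i + 1], ts1.present[i : i + 1]),
                                           TrackSet(ts2.positions[j : j + 1], ts2.present[j : j + 1]), eps)
                      for j in range(m2)] for i in range(m1)])
    candidates = list(range(m2)) + [-1] * m1  # -1 = leave track unmatched
    best = np.inf
    for assign in permutations(candidates, m1):
        used = [a for a in assign if a >= 0]
        if len(set(used)) != len(used):
            continue
        total = sum(cost[i, a] if a >= 0 else eps * N for i, a in enumerate(assign))
        total += eps * N * (m2 - len(used))
        best = min(best, total)
    return best


def random_trackset(rng, n_tracks, n_frames, missing=0.0, dim=2):
    pos = rng.uniform(0, 2000, size=(n_tracks, n_frames, dim))
    present = rng.random((n_tracks, n_frames)) >= missing
    for m in range(n_tracks):  # keep every track observed at least once
        if not present[m].any():
            present[m, rng.integers(n_frames)] = True
    pos = pos.astype(float)
    full = np.full((n_tracks, n_frames, 3), np.nan)
    full[..., :dim] = pos
    full[~present] = np.nan
    return TrackSet(full, present)


class TestGatedDistance:
    def test_identity_is_zero(self):
        t = np.random.default_rng(0).uniform(0, 1000, (5, 2))
        assert gated_track_distance(t, t, GATE_5PX) == 0.0

    def test_gate_saturates_large_offsets(self):
        # constant 10-pixel offset capped at the 5-pixel gate
        n = 7
        a = np.zeros((n, 2))
        b = np.tile([10 * PIXEL, 0.0], (n, 1))
        assert gated_track_distance(a, b, GATE_5PX) == pytest.approx(GATE_5PX * n)

    def test_missing_detection_costs_one_gate(self):
        # identical 22-frame tracks except one missing frame: total is eps
        n = 22
        a = np.tile([400.0, 400.0], (n, 1))
        b = a.copy()
        b[7] = np.nan
        assert gated_track_distance(a, b, GATE_5PX) == pytest.approx(GATE_5PX)

    def test_infinite_gate_forbids_missing_frames(self):
        a = np.zeros((3, 2))
        b = a.copy()
        b[1] = np.nan
        with pytest.raises(ValueError):
            gated_track_distance(a, b, np.inf)

    def test_frame_axis_mismatch(self):
        with pytest.raises(ValueError):
            gated_track_distance(np.zeros((3, 2)), np.zeros((4, 2)), 100.0)


class TestPairing:
    def test_single_pair(self):
        rng = np.random.default_rng(1)
        a, b = random_trackset(rng, 1, 6), random_trackset(rng, 1, 6)
        res = pair_track_sets(a, b, GATE_5PX)
        assert res.pairs == ((0, 0),)
        assert res.total == pytest.approx(
            gated_track_distance(a.positions[0, :, :2], b.positions[0, :, :2], GATE_5PX)
        )

    @pytest.mark.parametrize("m1,m2,missing", [(3, 4, 0.0), (4, 3, 0.2), (2, 2, 0.3), (1, 4, 0.0)])
    def test_matches_exhaustive_enumeration(self, m1, m2, missing):
        rng = np.random.default_rng(10 * m1 + m2)
        for _ in range(20):
            a = random_trackset(rng, m1, 5, missing)
            b = random_trackset(rng, m2, 5, missing)
            res = pair_track_sets(a, b, GATE_5PX)
            assert res.total == pytest.approx(brute_pairing_total(a, b, GATE_5PX), rel=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = random_trackset(rng, 3, 5), random_trackset(rng, 4, 5)
        assert pair_track_sets(a, b, GATE_5PX).total == pytest.approx(pair_track_sets(b, a, GATE_5PX).total)

    def test_unmatched_tracks_charged_one_gate_per_frame(self):
        n = 5
        a = TrackSet(np.zeros((1, n, 2)))
        b = TrackSet(np.stack([np.zeros((n, 2)), np.full((n, 2), 1e6)]))
        res = pair_track_sets(a, b, GATE_5PX)
        assert res.unmatched_2 == (1,)
        assert res.total == pytest.approx(GATE_5PX * n)


class TestTrackingError:
    def test_identical_sets(self):
        a = random_trackset(np.random.default_rng(2), 3, 6)
        assert tracking_error(a, a, GATE_5PX) == 0.0

    def test_constant_offset_below_gate(self):
        # a single track at a constant 37 nm offset: error is 37 nm
        n = 10
        a = TrackSet(np.zeros((1, n, 2)))
        b = TrackSet(np.tile([37.0, 0.0], (n, 1))[None])
        assert tracking_error(a, b, GATE_5PX) == pytest.approx(37.0)

    def test_unmatched_reference_track(self):
        # 2 estimated vs 3 reference: the unmatched reference costs eps*N
        rng = np.random.default_rng(3)
        n = 6
        est = random_trackset(rng, 2, n)
        ref = random_trackset(rng, 3, n)
        total = brute_pairing_total(est, ref, GATE_5PX)
        assert tracking_error(est, ref, GATE_5PX) == pytest.approx(total / (n * 3))

    def test_empty_reference_rejected(self):
        a = random_trackset(np.random.default_rng(4), 1, 3)
        b = TrackSet(np.zeros((0, 3, 2)), np.zeros((0, 3), bool))
        with pytest.raises(ValueError):
            tracking_error(a, b, GATE_5PX)

    def test_gate_monotonicity(self):
        rng = np.random.default_rng(5)
        a, b = random_trackset(rng, 3, 6, 0.15), random_trackset(rng, 3, 6, 0.15)
        errs = [tracking_error(a, b, g) for g in (2 * PIXEL, 5 * PIXEL, 10 * PIXEL)]
        assert np.all(np.diff(errs) >= 0)
        assert 0 <= errs[0] <= 2 * PIXEL


class TestDualView:
    def test_identical_views(self):
        a = random_trackset(np.random.default_rng(6), 2, 5)
        assert dual_view_tracking_error(a, a) == 0.0

    def test_pairing_distance_is_halved(self):
        # per-frame separation 136.4 nm between the views reads as a
        # 68.2 nm error against the (unobserved) common ground truth
        n = 22
        a = TrackSet(np.zeros((1, n, 2)))
        b = TrackSet(np.tile([136.4, 0.0], (n, 1))[None])
        assert dual_view_tracking_error(a, b) == pytest.approx(68.2)

    def test_constant_74nm_offset(self):
        n = 8
        a = TrackSet(np.zeros((1, n, 2)))
        b = TrackSet(np.tile([0.0, 74.0], (n, 1))[None])
        assert dual_view_tracking_error(a, b) == pytest.approx(37.0)

    def test_unequal_counts_use_mean(self):
        n = 4
        a = TrackSet(np.zeros((1, n, 2)))
        b = TrackSet(np.stack([np.zeros((n, 2)), np.full((n, 2), 500.0)]))
        res = dual_view_tracking_error(a, b)
        assert res == pytest.approx(0.0 / (2 * n * 1.5))

    def test_missing_detections_rejected(self):
        pos = np.zeros((1, 4, 2))
        pos[0, 2] = np.nan
        with pytest.raises(ValueError):
            dual_view_tracking_error(TrackSet(pos), TrackSet(np.zeros((1, 4, 2))))


class TestLocalizationResolution:
    def test_identity(self):
        a = random_trackset(np.random.default_rng(8), 2, 5)
        assert localization_resolution(a, a) == 0.0

    def test_insensitive_to_mislinks(self):
        # swapping labels from frame k onward is a pure linking error:
        # resolution is unchanged while tracking error grows
        rng = np.random.default_rng(9)
        truth = random_trackset(rng, 2, 8)
        swapped = truth.positions.copy()
        swapped[:, 4:] = swapped[::-1, 4:]
        mislinked = TrackSet(swapped)
        assert localization_resolution(mislinked, truth) == pytest.approx(0.0, abs=1e-9)
        assert tracking_error(mislinked, truth, GATE_5PX) > 0

    def test_matches_per_frame_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            a, b = random_trackset(rng, 2, 5), random_trackset(rng, 2, 5)
            per_frame = []
            for n in range(5):
                d = np.linalg.norm(a.positions[:, n, None, :2] - b.positions[None, :, n, :2], axis=-1)
                per_frame.append(min(d[0, 0] + d[1, 1], d[0, 1] + d[1, 0]))
            assert localization_resolution(a, b) == pytest.approx(sum(per_frame) / 10)

    def test_unequal_counts_undefined(self):
        rng = np.random.default_rng(11)
        a, b = random_trackset(rng, 2, 4), random_trackset(rng, 3, 4)
        with pytest.raises(ValueError):
            localization_resolution(a, b)

    def test_never_exceeds_tracking_error(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a, b = random_trackset(rng, 3, 6), random_trackset(rng, 3, 6)
            assert localization_resolution(a, b) <= tracking_error(a, b, np.inf) + 1e-9


class TestDimensionHandling:
    def test_mixed_dimensionality_compares_lateral_only(self):
        rng = np.random.default_rng(13)
        xy = rng.uniform(0, 1000, (1, 5, 2))
        xyz = np.concatenate([xy, rng.uniform(-300, 300, (1, 5, 1))], axis=-1)
        assert gated_track_distance(TrackSet(xy), TrackSet(xyz), GATE_5PX) == pytest.approx(0.0)

    def test_axial_compared_as_magnitude(self):
        n = 4
        a = np.zeros((1, n, 3))
        a[..., 2] = 250.0
        b = np.zeros((1, n, 3))
        b[..., 2] = -250.0
        assert gated_track_distance(TrackSet(a), TrackSet(b), GATE_5PX) == pytest.approx(0.0)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), m1=st.integers(1, 3), m2=st.integers(1, 3))
def test_pairing_oracle_property(seed, m1, m2):
    """Assignment solution equals the exhaustive minimum for arbitrary
    small random instances."""
    rng = np.random.default_rng(seed)
    a = random_trackset(rng, m1, 4, missing=0.1)
    b = random_trackset(rng, m2, 4, missing=0.1)
    res = pair_track_sets(a, b, GATE_5PX)
    assert res.total == pytest.approx(brute_pairing_total(a, b, GATE_5PX), rel=1e-12)
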