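"""Thin-plate-spline fitting, ghost propagation and tracklet stitching."""

import numpy as np
import pytest

from nervetrack.stitching import (
    StitchConfig,
    fit_tps,
    propagate_positions,
    stitch_tracklets,
)
from nervetrack.synthetic import ContractionConfig, SyntheticConfig, generate_trajectories
from nervetrack.tracking import Tracklet


def make_tracklet(tid, start, positions):
    positions = np.asarray(positions, dtype=float)
    L = len(positions)
    return Tracklet(
        id=tid, start_frame=start, positions=positions,
        interpolated=np.zeros(L, bool), detection_labels=np.zeros(L, int),
    )


class TestFitTPS:
    def test_zero_displacements_give_zero_map(self, rng):
        pts = rng.uniform(0, 100, size=(10, 2))
        tps = fit_tps(pts, np.zeros((10, 2)), alpha=0.0)
        q = rng.uniform(0, 100, size=(20, 2))
        assert np.allclose(tps(q), 0.0, atol=1e-9)

    def test_affine_recovered_exactly_at_alpha_zero(self, rng):
        A = np.array([[1.01, 0.02], [-0.03, 0.99]])
        b = np.array([2.0, -1.0])
        pts = rng.uniform(0, 100, size=(20, 2))
        disp = pts @ A.T + b - pts
        tps = fit_tps(pts, disp, alpha=0.0)
        q = rng.uniform(10, 90, size=(8, 2))
        assert np.max(np.abs(tps(q) - (q @ A.T + b - q))) < 1e-6

    def test_large_alpha_approaches_affine_regression(self, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        disp = 0.02 * pts + rng.normal(0, 0.5, size=(20, 2))
        tps = fit_tps(pts, disp, alpha=1e9)
        M = np.column_stack([pts, np.ones(len(pts))])
        coef, *_ = np.linalg.lstsq(M, disp, rcond=None)
        q = rng.uniform(10, 90, size=(10, 2))
        affine = q @ coef[:2] + coef[2]
        assert np.max(np.abs(tps(q) - affine)) < 1e-3

    def test_degenerate_inputs_fall_back_to_affine(self):
        # two points: translation fallback
        tps = fit_tps(np.array([[0.0, 0.0], [1.0, 1.0]]),
                      np.array([[2.0, 0.0], [2.0, 0.0]]))
        assert tps.degenerate
        assert np.allclose(tps([[5.0, 5.0]]), [[2.0, 0.0]])
        # collinear points
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        tps2 = fit_tps(pts, np.tile([1.0, 1.0], (4, 1)))
        assert tps2.degenerate


class TestPropagation:
    def test_uniform_translation_field(self):
        tks = [
            make_tracklet(i, 0, [[10.0 + 5 * i, 10.0 + t] for t in range(20)])
            for i in range(5)
        ]
        tks.append(make_tracklet(5, 0, [[5.0, 5.0 + t] for t in range(11)]))
        fwd, _ = propagate_positions(tks, StitchConfig(alpha=0.0, max_gap=10))
        # tracklet 5 ends at frame 10 at col 15; ghost at frame 13 -> col 18
        assert np.allclose(fwd[5][13], [5.0, 18.0], atol=1e-6)

    def test_static_field_keeps_last_position(self):
        tks = [
            make_tracklet(i, 0, [[10.0 + 7 * i, 40.0]] * 20) for i in range(4)
        ]
        tks.append(make_tracklet(4, 0, [[25.0, 25.0]] * 12))
        fwd, bwd = propagate_positions(tks, StitchConfig(max_gap=8))
        for f in range(12, 19):
            assert np.allclose(fwd[4][f], [25.0, 25.0], atol=1e-9)

    def test_rotation_field_propagates_on_circle(self, rng):
        theta = np.deg2rad(1.0)
        center = np.array([50.0, 50.0])

        def rot(p, t):
            a = theta * t
            R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            return (p - center) @ R.T + center

        base = rng.uniform(20, 80, size=(15, 2))
        T = 20
        tks = [
            make_tracklet(i, 0, [rot(base[i], t) for t in range(T)])
            for i in range(15)
        ]
        endpoint = np.array([30.0, 60.0])
        tks.append(make_tracklet(15, 0, [rot(endpoint, t) for t in range(11)]))
        fwd, _ = propagate_positions(tks, StitchConfig(alpha=0.0, max_gap=10))
        assert np.linalg.norm(fwd[15][15] - rot(endpoint, 15)) < 0.1


class TestStitch:
    def test_split_track_is_rejoined(self, rng):
        # one neuron split 0-40 / 46-100 under uniform translation, with 20
        # continuous witnesses
        T = 101
        tks = []
        for i in range(20):
            start = rng.uniform(10, 80, size=2)
            tks.append(
                make_tracklet(i, 0, [start + [0.2 * t, 0.1 * t] for t in range(T)])
            )
        p0 = np.array([50.0, 50.0])
        path = [p0 + [0.2 * t, 0.1 * t] for t in range(T)]
        tks.append(make_tracklet(20, 0, path[:41]))
        tks.append(make_tracklet(21, 46, path[46:]))
        tracks = stitch_tracklets(tks, StitchConfig(alpha=10, eta=5, max_gap=50))
        merged = [tr for tr in tracks if set(tr.tracklet_ids) == {20, 21}]
        assert len(merged) == 1
        tr = merged[0]
        assert (tr.start_frame, tr.end_frame) == (0, 100)
        # gap frames are flagged and close to the true path
        gap = tr.gap_filled
        assert gap.sum() == 5
        for f in range(41, 46):
            assert np.linalg.norm(tr.position_at(f) - path[f]) < 1.0

    def test_distant_ghosts_not_stitched(self):
        tks = [
            make_tracklet(0, 0, [[10.0, 10.0]] * 10),
            make_tracklet(1, 15, [[10.0, 24.0]] * 10),  # 14 px away > 2 eta
        ]
        tracks = stitch_tracklets(tks, StitchConfig(eta=5.0))
        assert len(tracks) == 2

    def test_assignment_matches_exhaustive_choice(self):
        # A (0-10) can continue into B (15-30, ghost distance ~1) or
        # C (16-31, ghost distance ~4): optimal assignment links A-B
        tks = [
            make_tracklet(0, 0, [[20.0, 20.0]] * 11),
            make_tracklet(1, 15, [[20.0, 21.0]] * 16),
            make_tracklet(2, 16, [[20.0, 24.0]] * 16),
        ]
        tracks = stitch_tracklets(tks, StitchConfig(eta=5.0, max_gap=20))
        chains = sorted(tuple(tr.tracklet_ids) for tr in tracks)
        assert (0, 1) in chains
        assert (2,) in chains

    def test_detected_positions_never_altered(self, rng):
        cfg = SyntheticConfig(
            n_neurons=20, n_nematocytes=0, T=200, H=192, W=192, seed=2,
            contraction=ContractionConfig(n_events=0),
        )
        traj, _ = generate_trajectories(cfg)
        tks = []
        tid = 0
        originals = {}
        for i in range(20):
            cut = int(rng.integers(60, 120))
            for s, e in ((0, cut - 1), (cut + 12, cfg.T - 1)):
                tk = make_tracklet(tid, s, traj[i, s : e + 1].copy())
                originals[tid] = tk.positions.copy()
                tks.append(tk)
                tid += 1
        tracks = stitch_tracklets(tks, StitchConfig())
        for tr in tracks:
            for tk_id in tr.tracklet_ids:
                tk = next(t for t in tks if t.id == tk_id)
                for k in range(len(tk)):
                    f = tk.start_frame + k
                    assert np.array_equal(tr.position_at(f), originals[tk_id][k])

    def test_dropout_rejoin_rates(self, rng):
        cfg = SyntheticConfig(
            n_neurons=40, n_nematocytes=0, T=600, H=256, W=256, seed=11,
            contraction=ContractionConfig(n_events=0),
        )
        traj, _ = generate_trajectories(cfg)
        tks, owner, tid = [], {}, 0
        for i in range(40):
            dur = int(rng.integers(10, 21))
            start = int(rng.integers(80, cfg.T - 80 - dur))
            for s, e in ((0, start - 1), (start + dur, cfg.T - 1)):
                tks.append(make_tracklet(tid, s, traj[i, s : e + 1].copy()))
                owner[tid] = i
                tid += 1
        tracks = stitch_tracklets(tks, StitchConfig(alpha=10, eta=5))
        correct = wrong = 0
        for tr in tracks:
            cells = [owner[t] for t in tr.tracklet_ids]
            for a, b in zip(cells[:-1], cells[1:]):
                if a == b:
                    correct += 1
                else:
                    wrong += 1
        assert correct / 40 >= 0.95
        assert wrong / 40 < 0.02
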