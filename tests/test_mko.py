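"""Multibody kinematic optimization: solver correctness and properties."""
import numpy as np
import pytest

import limbkin as lk
from limbkin.containers import QTrajectory
from limbkin.mko import WeightScheme, solve_frame, static_initializer
from limbkin.model import marker_positions, rot_zxy
from limbkin.synth import guard_posture

from conftest import random_valid_q


def _markers_dict(chain, q):
    return dict(zip(chain.marker_labels, marker_positions(chain, q)))


class TestSolveFrame:
    def test_zero_residual_fixed_point(self, chain, rng):
        q_true = random_valid_q(chain, rng)
        q_est, rep = solve_frame(chain, _markers_dict(chain, q_true), q_init=q_true)
        assert rep.objective < 1e-16
        assert np.allclose(q_est, q_true, atol=1e-9)

    def test_basin_of_attraction_from_guard(self, chain, rng):
        """Recover q* from inits perturbed up to 30 deg on every DoF."""
        for _ in range(40):
            q_true = static_initializer(chain) + rng.uniform(-0.45, 0.45, chain.n_q)
            for side in ("L", "R"):
                k = chain.q_index[(f"elbow_{side}", "flex_ext")]
                q_true[k] = rng.uniform(0.2, 2.2)
            markers = _markers_dict(chain, q_true)
            q_init = q_true + rng.uniform(-0.5, 0.5, chain.n_q)
            q_est, _ = solve_frame(chain, markers, q_init=q_init)
            assert np.max(np.abs(q_est - q_true)) < 1e-6

    def test_duplicate_marker_with_halved_weight_same_solution(self, chain, rng):
        q_true = random_valid_q(chain, rng)
        markers = _markers_dict(chain, q_true)
        q_init = q_true + 0.1
        base, _ = solve_frame(chain, markers, q_init=q_init)
        # duplicating HND_L and halving both copies' weights is equivalent
        dup = chain.copy()
        seg, pos = dup.marker_local_positions["HND_L"]
        dup.marker_local_positions["HND_L2"] = (seg, pos.copy())
        dup._finalize()
        markers2 = dict(markers)
        markers2["HND_L2"] = markers["HND_L"]
        w = WeightScheme(marker_overrides={"HND_L": 0.5, "HND_L2": 0.5})
        q_dup, _ = solve_frame(dup, markers2, weights=w, q_init=q_init)
        assert np.allclose(q_dup, base, atol=1e-8)

    def test_nan_markers_excluded_with_warning(self, chain, rng):
        q_true = random_valid_q(chain, rng)
        markers = _markers_dict(chain, q_true)
        markers["HUM_L"] = np.array([np.nan, np.nan, np.nan])
        q_est, rep = solve_frame(chain, markers, q_init=q_true)
        assert np.isnan(rep.residual_norms["HUM_L"])
        assert np.allclose(q_est, q_true, atol=1e-7)

    def test_too_few_markers_rejected(self, chain):
        markers = {"SJN": np.zeros(3), "C7": np.ones(3)}
        with pytest.raises(ValueError, match="at least 3"):
            solve_frame(chain, markers)

    def test_collinear_markers_rejected(self, chain):
        markers = {
            lab: np.array([0.0, float(i), 0.0]) for i, lab in enumerate(chain.marker_labels)
        }
        with pytest.raises(ValueError, match="collinear"):
            solve_frame(chain, markers)

    def test_objective_equals_weighted_residual_sum(self, chain, rng):
        q_true = random_valid_q(chain, rng)
        markers = _markers_dict(chain, q_true)
        noisy = {k: v + rng.normal(0, 0.002, 3) for k, v in markers.items()}
        _q, rep = solve_frame(chain, noisy, q_init=q_true)
        w = WeightScheme.default()
        total = sum(
            w.weight_for(lab, chain.marker_local_positions[lab][0]) * rep.residual_norms[lab] ** 2
            for lab in chain.marker_labels
        )
        assert rep.objective == pytest.approx(total, abs=1e-12)

    def test_rigid_transform_invariance(self, chain, rng):
        """A common rigid transform of all markers moves only the root pose."""
        q_true = random_valid_q(chain, rng)
        markers = marker_positions(chain, q_true)
        R = rot_zxy(0.4, -0.3, 0.6)
        t = np.array([0.5, 1.0, -0.7])
        moved = (R @ markers.T).T + t
        q_init = q_true.copy()
        q_init[:3] = R @ q_true[:3] + t
        q_a, _ = solve_frame(chain, markers, q_init=q_true)
        q_b, _ = solve_frame(chain, moved, q_init=q_init)
        assert np.allclose(q_a[6:], q_b[6:], atol=1e-8)  # joint angles unchanged


class TestSolveTrajectory:
    def _noise_free_trial(self, chain, n=40, seed=3):
        script = lk.PunchScript(repetitions=1, peak_hand_speed=6.0, lead_in=0.1)
        qt = lk.generate_q_trajectory(chain, script, 300.0, seed=seed)
        qt = QTrajectory(qt.q[:n], 300.0)
        return qt, lk.render_markers(chain, qt)

    def test_noise_free_roundtrip(self, chain):
        qt, markers = self._noise_free_trial(chain)
        q_est, rep = lk.solve_trajectory(chain, markers)
        assert q_est.n_frames == markers.n_frames
        assert np.all(q_est.valid)
        assert np.max(np.abs(q_est.q - qt.q)) < 1e-5
        assert np.all(rep.converged)

    def test_single_frame_equals_solve_frame(self, chain):
        qt, markers = self._noise_free_trial(chain, n=1)
        q_traj, _ = lk.solve_trajectory(chain, markers)
        q_single, _ = solve_frame(
            chain, markers.frame(0), q_init=static_initializer(chain)
        )
        assert np.allclose(q_traj.q[0], q_single, atol=1e-10)

    def test_reversed_time_gives_reversed_solution(self, chain):
        qt, markers = self._noise_free_trial(chain)
        fwd, _ = lk.solve_trajectory(chain, markers)
        rev_markers = markers.copy()
        rev_markers.data = rev_markers.data[::-1].copy()
        rev, _ = lk.solve_trajectory(chain, rev_markers)
        assert np.allclose(rev.q[::-1], fwd.q, atol=1e-6)

    def test_gap_frames_flagged_invalid_not_interpolated(self, chain):
        qt, markers = self._noise_free_trial(chain, n=10)
        markers.data[4] = np.nan  # all markers missing on frame 4
        q_est, _ = lk.solve_trajectory(chain, markers)
        assert not q_est.valid[4]
        assert np.all(np.isnan(q_est.q[4]))
        assert q_est.valid[[0, 1, 2, 3, 5, 6, 7, 8, 9]].all()

    def test_noise_increases_joint_angle_error_monotonically(self, chain):
        """Marker noise sigma up -> angle RMSE up (small Monte-Carlo)."""
        qt, clean = self._noise_free_trial(chain, n=12)
        rmse = []
        for sigma in (0.0, 0.002, 0.005):
            errs = []
            for rep_i in range(3):
                noisy = clean.copy()
                if sigma > 0:
                    rng = np.random.default_rng(100 * rep_i + int(sigma * 1e4))
                    noisy.data = noisy.data + rng.normal(0, sigma, noisy.data.shape)
                q_est, _ = lk.solve_trajectory(chain, noisy)
                errs.append(np.sqrt(np.mean((q_est.q[:, 6:] - qt.q[:, 6:]) ** 2)))
            rmse.append(np.mean(errs))
        assert rmse[0] < rmse[1] < rmse[2]


class TestTuneWeights:
    def test_single_candidate_returned(self, chain):
        script = lk.PunchScript(repetitions=1, peak_hand_speed=5.0, lead_in=0.1)
        qt = lk.generate_q_trajectory(chain, script, 300.0, seed=4)
        markers = lk.render_markers(chain, QTrajectory(qt.q[:5], 300.0))
        only = WeightScheme.default()
        assert lk.tune_weights(chain, markers, [only]) is only

    def test_noise_free_tie_returns_first(self, chain):
        script = lk.PunchScript(repetitions=1, peak_hand_speed=5.0, lead_in=0.1)
        qt = lk.generate_q_trajectory(chain, script, 300.0, seed=4)
        markers = lk.render_markers(chain, QTrajectory(qt.q[:5], 300.0))
        first = WeightScheme(segment_weights={"thorax": 1, "clavicle": 1, "upper_arm": 1, "forearm": 1, "hand": 1}, name="uniform")
        second = WeightScheme.default()
        assert lk.tune_weights(chain, markers, [first, second]) is first

    def test_hand_noise_selects_hand_downweighting_scheme(self, chain):
        script = lk.PunchScript(repetitions=1, peak_hand_speed=5.0, lead_in=0.1)
        qt = lk.generate_q_trajectory(chain, script, 300.0, seed=4)
        markers = lk.render_markers(chain, QTrajectory(qt.q[:8], 300.0))
        rng = np.random.default_rng(0)
        for j, lab in enumerate(markers.labels):
            if lab.startswith("HND"):
                markers.data[:, j] += rng.normal(0, 0.02, (markers.n_frames, 3))
        uniform = WeightScheme(
            segment_weights={b: 1.0 for b in ("thorax", "clavicle", "upper_arm", "forearm", "hand")},
            name="uniform",
        )
        thorax_heavy = WeightScheme(name="thorax-heavy")  # default ordering
        best = lk.tune_weights(chain, markers, [uniform, thorax_heavy])
        assert best is thorax_heavy

    def test_empty_candidates_rejected(self, chain):
        with pytest.raises(ValueError):
            lk.tune_weights(chain, None, [])

    def test_default_ordering_thorax_heaviest(self):
        w = WeightScheme.default().segment_weights
        assert w["thorax"] > w["upper_arm"] > w["forearm"] > w["hand"]


class TestExportPoses:
    def test_identity_q_gives_template(self, chain):
        q = QTrajectory(np.zeros((3, chain.n_q)), 60.0)
        stream = lk.export_poses(chain, q)
        assert stream.n_frames == 3
        template = lk.forward_kinematics(chain, chain.q_zero())
        for s, seg in enumerate(stream.segments):
            assert np.allclose(stream.data[0, s], template[seg])

    def test_roundtrip_with_cardan_extraction(self, chain, rng):
        q = np.array([random_valid_q(chain, rng) for _ in range(4)])
        stream = lk.export_poses(chain, QTrajectory(q, 60.0))
        angles = lk.joint_angle_series(stream, chain, mirror_left=False)
        for k in range(4):
            for side in ("L", "R"):
                got = angles[("shoulder", side)][k]
                # shoulder series spans sternoclavicular + glenohumeral; use
                # a q with zero clavicle DoFs to compare directly
        q0 = np.array([random_valid_q(chain, rng) for _ in range(4)])
        for key, idx in chain.q_index.items():
            if key[0].startswith("sternoclavicular"):
                q0[:, idx] = 0.0
        stream = lk.export_poses(chain, QTrajectory(q0, 60.0))
        angles = lk.joint_angle_series(stream, chain, mirror_left=False)
        for k in range(4):
            for side in ("L", "R"):
                for ai, dof in enumerate(("flex_ext", "abd_add", "int_ext")):
                    expected = q0[k, chain.q_index[(f"shoulder_{side}", dof)]]
                    assert angles[("shoulder", side)][k, ai] == pytest.approx(
                        expected, abs=1e-9
                    )
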