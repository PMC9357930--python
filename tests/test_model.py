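"""Chain construction, forward kinematics, joint centers, scaling."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import limbkin as lk
from limbkin.model import (
    _fk_array,
    check_pose,
    marker_jacobian,
    marker_positions,
    rot_zxy,
)

from conftest import random_valid_q


class TestBuildChain:
    def test_topology_and_dof_counts(self, chain):
        assert chain.n_q == 24
        root = chain.joint("ground_thorax")
        assert len(root.free_rotations) == 3 and len(root.free_translations) == 3
        for side in ("L", "R"):
            assert len(chain.joint(f"sternoclavicular_{side}").free_rotations) == 2
            assert set(chain.joint(f"shoulder_{side}").free_rotations) == {
                "flex_ext", "abd_add", "int_ext",
            }
            elbow = chain.joint(f"elbow_{side}")
            assert set(elbow.free_rotations) == {"flex_ext", "int_ext"}
            assert "abd_add" not in elbow.free_rotations
            wrist = chain.joint(f"wrist_{side}")
            assert set(wrist.free_rotations) == {"flex_ext", "abd_add"}
            assert "int_ext" not in wrist.free_rotations

    def test_every_marker_attaches_to_one_segment(self, chain):
        assert len(chain.marker_labels) == 21
        for lab, (seg, pos) in chain.marker_local_positions.items():
            assert seg in chain.segment_names
            assert np.all(np.isfinite(pos))

    def test_deterministic_field_for_field(self, profile):
        a = lk.build_chain(profile)
        b = lk.build_chain(profile)
        for sa, sb in zip(a.segments, b.segments):
            assert sa.name == sb.name and sa.length == sb.length
            assert np.array_equal(sa.com_offset, sb.com_offset)
        for ja, jb in zip(a.joints, b.joints):
            assert ja.name == jb.name
            assert np.array_equal(ja.offset_in_parent, jb.offset_in_parent)

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            lk.AnthroProfile("other", 1.8, 70.0)

    def test_overrides_replace_lengths(self, profile):
        c = lk.build_chain(profile, overrides={"upper_arm": 0.4})
        assert c.segment("upper_arm_L").length == pytest.approx(0.4)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            lk.AnthroProfile("male", -1.0, 70.0)
        with pytest.raises(ValueError):
            lk.AnthroProfile("male", 1.8, 0.0)


class TestForwardKinematics:
    def test_zero_q_gives_template_pose(self, chain):
        poses = lk.forward_kinematics(chain, chain.q_zero())
        for name, T in poses.items():
            check_pose(T)
            assert np.allclose(T[:3, :3], np.eye(3), atol=1e-12)
        # template: shoulder sits lateral of the sternoclavicular joint
        assert poses["upper_arm_R"][2, 3] > poses["thorax"][2, 3]

    def test_root_translation_shifts_everything(self, chain, rng):
        q = random_valid_q(chain, rng)
        delta = np.array([0.3, -0.2, 0.5])
        q2 = q.copy()
        q2[:3] += delta
        p1 = lk.forward_kinematics(chain, q)
        p2 = lk.forward_kinematics(chain, q2)
        for name in p1:
            assert np.allclose(p2[name][:3, 3] - p1[name][:3, 3], delta, atol=1e-12)
            assert np.allclose(p2[name][:3, :3], p1[name][:3, :3], atol=1e-12)

    def test_dimension_mismatch_rejected(self, chain):
        with pytest.raises(ValueError, match="length"):
            lk.forward_kinematics(chain, np.zeros(chain.n_q - 1))

    def test_pose_invariants_for_random_q(self, chain, rng):
        for _ in range(20):
            q = random_valid_q(chain, rng, scale=1.2)
            for T in lk.forward_kinematics(chain, q).values():
                check_pose(T, tol=1e-9)

    def test_cardan_roundtrip_recovers_joint_angles(self, chain, rng):
        """FK then relative-rotation decomposition returns exactly q."""
        for _ in range(10):
            q = random_valid_q(chain, rng)
            poses = lk.forward_kinematics(chain, q)
            for side in ("L", "R"):
                ang, gim = lk.cardan_angles(
                    poses[f"clavicle_{side}"], poses[f"upper_arm_{side}"]
                )
                assert not gim
                for k, dof in enumerate(("flex_ext", "abd_add", "int_ext")):
                    assert ang[k] == pytest.approx(
                        q[chain.q_index[(f"shoulder_{side}", dof)]], abs=1e-10
                    )

    def test_locked_dofs_produce_zero_cardan_components(self, chain, rng):
        for _ in range(5):
            q = random_valid_q(chain, rng)
            poses = lk.forward_kinematics(chain, q)
            for side in ("L", "R"):
                elbow, _ = lk.cardan_angles(
                    poses[f"upper_arm_{side}"], poses[f"forearm_{side}"]
                )
                wrist, _ = lk.cardan_angles(
                    poses[f"forearm_{side}"], poses[f"hand_{side}"]
                )
                assert abs(elbow[1]) < 1e-10  # elbow abd/add locked
                assert abs(wrist[2]) < 1e-10  # wrist int/ext locked

    def test_fk_preserves_interjoint_distances(self, chain, rng):
        ref = None
        for _ in range(10):
            q = random_valid_q(chain, rng, scale=1.0)
            centers = lk.joint_centers(lk.forward_kinematics(chain, q), chain)
            d = [
                np.linalg.norm(centers["shoulder_L"] - centers["elbow_L"]),
                np.linalg.norm(centers["elbow_L"] - centers["wrist_L"]),
                np.linalg.norm(centers["shoulder_R"] - centers["elbow_R"]),
            ]
            if ref is None:
                ref = d
            assert np.allclose(d, ref, atol=1e-10)

    def test_analytic_jacobian_matches_finite_differences(self, chain, rng):
        q = random_valid_q(chain, rng)
        J = marker_jacobian(chain, q)
        eps = 1e-7
        for j in range(chain.n_q):
            dq = np.zeros(chain.n_q)
            dq[j] = eps
            col = (marker_positions(chain, q + dq) - marker_positions(chain, q - dq)) / (2 * eps)
            assert np.allclose(J[:, :, j], col, atol=1e-6)


class TestJointCenters:
    def test_identity_poses_give_local_coordinates(self, chain):
        poses = {s: np.eye(4) for s in chain.segment_names}
        centers = lk.joint_centers(poses, chain)
        for j in chain.joints[1:]:
            assert np.allclose(centers[j.name], j.offset_in_parent)

    def test_translation_equivariance(self, chain, rng):
        q = random_valid_q(chain, rng)
        poses = lk.forward_kinematics(chain, q)
        c1 = lk.joint_centers(poses, chain)
        delta = np.array([1.0, 2.0, 3.0])
        shifted = {}
        for k, T in poses.items():
            T2 = T.copy()
            T2[:3, 3] += delta
            shifted[k] = T2
        c2 = lk.joint_centers(shifted, chain)
        for name in c1:
            assert np.allclose(c2[name] - c1[name], delta, atol=1e-12)

    def test_rigid_transform_equivariance_via_root(self, chain, rng):
        """Moving only the root rigidly transforms all joint centers."""
        q = random_valid_q(chain, rng)
        q2 = q.copy()
        q2[:3] = [0.5, -0.1, 0.2]
        q2[3:6] = [0.4, 0.2, -0.3]
        q[:3] = 0
        q[3:6] = 0
        c1 = lk.joint_centers(lk.forward_kinematics(chain, q), chain)
        c2 = lk.joint_centers(lk.forward_kinematics(chain, q2), chain)
        R = rot_zxy(*q2[3:6])
        t = q2[:3]
        for name in c1:
            assert np.allclose(c2[name], R @ c1[name] + t, atol=1e-10)

    def test_elbow_center_is_epicondyle_midpoint(self, chain, rng):
        q = random_valid_q(chain, rng)
        poses = lk.forward_kinematics(chain, q)
        markers = lk.project_markers(chain, poses)
        centers = lk.joint_centers(poses, chain)
        for side in ("L", "R"):
            mid = 0.5 * (markers[f"EPL_{side}"] + markers[f"EPM_{side}"])
            assert np.allclose(centers[f"elbow_{side}"], mid, atol=1e-12)
            mid_w = 0.5 * (markers[f"RSP_{side}"] + markers[f"USP_{side}"])
            assert np.allclose(centers[f"wrist_{side}"], mid_w, atol=1e-12)

    def test_missing_pose_rejected_naming_joint(self, chain):
        poses = {s: np.eye(4) for s in chain.segment_names if s != "forearm_L"}
        with pytest.raises(ValueError, match="wrist_L"):
            lk.joint_centers(poses, chain)


class TestProjectMarkers:
    def test_identity_poses_give_locals(self, chain):
        poses = {s: np.eye(4) for s in chain.segment_names}
        markers = lk.project_markers(chain, poses)
        for lab, (seg, local) in chain.marker_local_positions.items():
            assert np.allclose(markers[lab], local)

    def test_rotating_one_segment_moves_only_its_markers(self, chain):
        poses = {s: np.eye(4) for s in chain.segment_names}
        ref = lk.project_markers(chain, poses)
        R = Rotation.from_euler("ZXY", [0.3, -0.2, 0.5]).as_matrix()
        T = np.eye(4)
        T[:3, :3] = R
        poses["hand_R"] = T
        out = lk.project_markers(chain, poses)
        for lab, (seg, local) in chain.marker_local_positions.items():
            if seg == "hand_R":
                assert np.allclose(out[lab], R @ local, atol=1e-12)
            else:
                assert np.allclose(out[lab], ref[lab])

    def test_planar_two_link_closed_form_hand_position(self, chain):
        """FK + projection matches the planar 2-link formula for the arm."""
        th_sh, th_el = 0.7, 0.9
        q = chain.q_zero()
        q[chain.q_index[("shoulder_R", "flex_ext")]] = th_sh
        q[chain.q_index[("elbow_R", "flex_ext")]] = th_el
        poses = lk.forward_kinematics(chain, q)
        centers = lk.joint_centers(poses, chain)
        L1 = chain.segment("upper_arm_R").length
        L2 = chain.segment("forearm_R").length
        shoulder = centers["shoulder_R"]
        # planar motion in the X-Y plane: flexion rotates the -Y long axis
        def link(theta):
            return np.array([np.sin(theta), -np.cos(theta), 0.0])

        wrist_expected = shoulder + L1 * link(th_sh) + L2 * link(th_sh + th_el)
        assert np.allclose(centers["wrist_R"], wrist_expected, atol=1e-12)


class TestScaleTemplate:
    def test_fixed_point_of_own_static(self, chain):
        q_static = chain.q_zero()
        for side in ("L", "R"):
            q_static[chain.q_index[(f"elbow_{side}", "flex_ext")]] = 0.4
        static = lk.project_markers(chain, lk.forward_kinematics(chain, q_static))
        scaled = lk.scale_template(chain, static)
        for s_new, s_old in zip(scaled.segments, chain.segments):
            assert s_new.length == pytest.approx(s_old.length, abs=1e-9)
        for lab in chain.marker_labels:
            assert np.allclose(
                scaled.marker_local_positions[lab][1],
                chain.marker_local_positions[lab][1],
                atol=1e-9,
            )

    def test_longer_arm_static_scales_upper_arm_length(self, profile, chain):
        """A subject whose upper-arm landmarks sit 10% farther apart."""
        long_arm = lk.build_chain(
            profile, overrides={"upper_arm": 1.10 * chain.segment("upper_arm_R").length}
        )
        q_static = long_arm.q_zero()
        for side in ("L", "R"):
            q_static[long_arm.q_index[(f"elbow_{side}", "flex_ext")]] = 0.4
        static = lk.project_markers(long_arm, lk.forward_kinematics(long_arm, q_static))
        scaled = lk.scale_template(chain, static)
        assert scaled.segment("upper_arm_R").length == pytest.approx(
            1.10 * chain.segment("upper_arm_R").length, rel=1e-4
        )
        assert scaled.segment("forearm_R").length == pytest.approx(
            chain.segment("forearm_R").length, rel=1e-4
        )

    def test_missing_landmarks_listed(self, chain):
        q_static = chain.q_zero()
        static = lk.project_markers(chain, lk.forward_kinematics(chain, q_static))
        del static["EPL_L"], static["HND_R"]
        with pytest.raises(ValueError, match="EPL_L"):
            lk.scale_template(chain, static)

    def test_empty_static_rejected(self, chain):
        from limbkin.containers import MarkerTrajectories

        empty = MarkerTrajectories(list(chain.marker_labels), np.empty((0, 21, 3)), 300.0)
        with pytest.raises(ValueError):
            lk.scale_template(chain, empty)
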