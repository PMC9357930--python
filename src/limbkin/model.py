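"""Upper-extremity multibody model and forward kinematics.

The chain is tree-structured: a six-DoF thorax root, then per side a
clavicle (two rotational DoF at the sternoclavicular joint), upper arm
(three-DoF shoulder), forearm (two-DoF elbow, abduction/adduction locked)
and hand (two-DoF wrist, internal/external rotation locked) - 24 DoF in
total for the bilateral chain.

Conventions
-----------
* Segment frames: X anterior, Y along the long axis (proximal to distal is
  -Y for the hanging arm), Z lateral to the right. In the template
  (anatomical) posture every segment frame is aligned with the global frame,
  so relative parent->child rotations are exactly the joint rotations.
* Global frame: right-handed, X anterior, Y vertical (up), Z to the right.
* Joint rotations: intrinsic Z-X-Y cardan sequence mapping to
  (flexion/extension, abduction/adduction, internal/external rotation).
  Locked DoFs contribute zero rotation and are absent from the coordinate
  vector q.
* q layout: root translation (3), root Z-X-Y orientation (3), then per side
  (left first) sternoclavicular (2), shoulder (3), elbow (2), wrist (2).

Units: meters and radians.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

SIDES = ("L", "R")
#: rotation DoF labels in intrinsic sequence order and their rotation axes
ROTATION_AXES = (("flex_ext", "z"), ("abd_add", "x"), ("int_ext", "y"))
_AXIS_OF = dict(ROTATION_AXES)

SEGMENT_BASES = ("thorax", "clavicle", "upper_arm", "forearm", "hand")

# marker label -> (segment base, local position builder); see build_chain
THORAX_MARKERS = ("SJN", "SXS", "C7", "T8", "T12")
SIDE_MARKERS = ("ACR", "HUM", "EPL", "EPM", "FRA", "RSP", "USP", "HND")


def _axis_rot(axis: str, a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    if axis == "z":
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    if axis == "x":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    if axis == "y":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    raise ValueError(f"unknown axis {axis!r}")


def rot_zxy(flex: float, abd: float, rot: float) -> np.ndarray:
    """Intrinsic Z-X-Y rotation matrix Rz(flex) @ Rx(abd) @ Ry(rot)."""
    return _axis_rot("z", flex) @ _axis_rot("x", abd) @ _axis_rot("y", rot)


def homogeneous(R: np.ndarray, t: np.ndarray) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = t
    return T


def check_pose(T: np.ndarray, tol: float = 1e-9) -> None:
    """Raise if T is not a valid homogeneous rigid transform."""
    T = np.asarray(T, dtype=float)
    if T.shape != (4, 4):
        raise ValueError(f"pose must be 4x4, got {T.shape}")
    R = T[:3, :3]
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("rotation block is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > max(tol, 1e-9):
        raise ValueError("rotation block has det != +1")
    if not np.allclose(T[3], [0.0, 0.0, 0.0, 1.0], atol=tol):
        raise ValueError("last row must be (0, 0, 0, 1)")


@dataclass(frozen=True)
class AnthroProfile:
    """Anthropometric inputs used to scale the generic template."""

    sex: str
    height: float  # m
    mass: float  # kg

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex label {self.sex!r}; use 'female' or 'male'")
        if not self.height > 0:
            raise ValueError("height must be positive")
        if not self.mass > 0:
            raise ValueError("mass must be positive")


@dataclass
class SegmentSpec:
    name: str
    length: float  # m, along the long axis
    com_offset: np.ndarray  # 3-vector in segment frame, m
    frame_definition: str = "identity-template"

    def __post_init__(self) -> None:
        self.com_offset = np.asarray(self.com_offset, dtype=float)
        if not self.length > 0:
            raise ValueError(f"segment {self.name}: length must be positive")
        if not np.all(np.isfinite(self.com_offset)):
            raise ValueError(f"segment {self.name}: com_offset must be finite")

    @property
    def base(self) -> str:
        return self.name.rsplit("_", 1)[0] if self.name != "thorax" else "thorax"


@dataclass
class JointConstraint:
    """A joint in the tree: child frame origin sits at ``offset_in_parent``.

    The joint center is that fixed point of the parent frame; free DoFs are
    the only entries of q, so locked DoFs are satisfied exactly.
    """

    name: str
    parent: str | None
    child: str
    free_rotations: tuple[str, ...]
    free_translations: tuple[str, ...]
    offset_in_parent: np.ndarray

    def __post_init__(self) -> None:
        self.offset_in_parent = np.asarray(self.offset_in_parent, dtype=float)
        for r in self.free_rotations:
            if r not in _AXIS_OF:
                raise ValueError(f"joint {self.name}: unknown rotation DoF {r!r}")
        for t in self.free_translations:
            if t not in ("x", "y", "z"):
                raise ValueError(f"joint {self.name}: unknown translation DoF {t!r}")

    @property
    def n_free(self) -> int:
        return len(self.free_rotations) + len(self.free_translations)


@dataclass
class KinematicChain:
    """Segment/joint topology, geometry and the marker map."""

    segments: list[SegmentSpec]
    joints: list[JointConstraint]
    marker_local_positions: dict[str, tuple[str, np.ndarray]]
    #: regression-style joint centers stored in a segment frame (thorax)
    extra_joint_centers: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)
    profile: AnthroProfile | None = None

    def __post_init__(self) -> None:
        self._finalize()

    # -- derived structure -------------------------------------------------
    def _finalize(self) -> None:
        self.segment_names = [s.name for s in self.segments]
        self._seg_index = {n: i for i, n in enumerate(self.segment_names)}
        if self.joints[0].parent is not None:
            raise ValueError("first joint must be the root joint")
        # q indexing: root translations, then rotations in sequence order
        q_index: dict[tuple[str, str], int] = {}
        k = 0
        root = self.joints[0]
        for t in root.free_translations:
            q_index[(root.name, "t" + t)] = k
            k += 1
        for dof, _ax in ROTATION_AXES:
            if dof in root.free_rotations:
                q_index[(root.name, dof)] = k
                k += 1
        for j in self.joints[1:]:
            if j.free_translations:
                raise ValueError(f"non-root joint {j.name} cannot translate")
            for dof, _ax in ROTATION_AXES:
                if dof in j.free_rotations:
                    q_index[(j.name, dof)] = k
                    k += 1
        self.q_index = q_index
        self.n_q = k

        # children map + topological check (tree: one parent joint each)
        child_joint: dict[str, JointConstraint] = {}
        for j in self.joints[1:]:
            if j.child in child_joint:
                raise ValueError(f"segment {j.child} has two parent joints")
            child_joint[j.child] = j
        for s in self.segment_names[1:]:
            if s not in child_joint:
                raise ValueError(f"segment {s} has no parent joint")

        for lab, (seg, _pos) in self.marker_local_positions.items():
            if seg not in self._seg_index:
                raise ValueError(f"marker {lab} attaches to unknown segment {seg}")

        # fast FK tables: non-root joints in segment order (parents first)
        self._fk_joints = []
        for j in self.joints[1:]:
            rots = [
                (self.q_index[(j.name, dof)], ax)
                for dof, ax in ROTATION_AXES
                if dof in j.free_rotations
            ]
            self._fk_joints.append(
                (self._seg_index[j.parent], self._seg_index[j.child], j.offset_in_parent, rots)
            )
        self._root_rot = [
            (self.q_index[(root.name, dof)], ax)
            for dof, ax in ROTATION_AXES
            if dof in root.free_rotations
        ]
        self._root_trans = [self.q_index[(root.name, "t" + t)] for t in root.free_translations]

        self.marker_labels = list(self.marker_local_positions)
        self._marker_seg = np.array(
            [self._seg_index[self.marker_local_positions[m][0]] for m in self.marker_labels]
        )
        self._marker_local = np.array(
            [self.marker_local_positions[m][1] for m in self.marker_labels]
        )
        # ancestors of each segment: indices into self._fk_joints along path
        parent_of = {self._seg_index[j.child]: self._seg_index[j.parent] for j in self.joints[1:]}
        joint_of_child = {e[1]: i for i, e in enumerate(self._fk_joints)}
        self._ancestor_joints: list[list[int]] = []
        for i in range(len(self.segments)):
            path = []
            k_ = i
            while k_ != 0:
                path.append(joint_of_child[k_])
                k_ = parent_of[k_]
            self._ancestor_joints.append(path[::-1])

    def joint(self, name: str) -> JointConstraint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    def segment(self, name: str) -> SegmentSpec:
        return self.segments[self._seg_index[name]]

    def q_zero(self) -> np.ndarray:
        return np.zeros(self.n_q)

    def copy(self) -> "KinematicChain":
        return KinematicChain(
            [replace(s, com_offset=s.com_offset.copy()) for s in self.segments],
            [replace(j, offset_in_parent=j.offset_in_parent.copy()) for j in self.joints],
            {m: (s, p.copy()) for m, (s, p) in self.marker_local_positions.items()},
            {n: (s, p.copy()) for n, (s, p) in self.extra_joint_centers.items()},
            self.profile,
        )


def load_anthro_table() -> dict:
    with importlib.resources.files("limbkin.data").joinpath("anthro.yaml").open() as fh:
        return yaml.safe_load(fh)


def build_chain(
    profile: AnthroProfile, overrides: Mapping[str, float] | None = None
) -> KinematicChain:
    """Build the bilateral upper-extremity chain scaled to a subject.

    Segment lengths come from the bundled sex-specific anthropometric table
    scaled by stature; ``overrides`` maps segment base names (e.g.
    ``"upper_arm"``) to lengths in meters that replace the table values.
    """
    table = load_anthro_table()[profile.sex]
    lengths = {b: table["length_frac"][b] * profile.height for b in SEGMENT_BASES}
    if overrides:
        for base, L in overrides.items():
            if base not in lengths:
                raise ValueError(f"unknown segment base {base!r} in overrides")
            lengths[base] = float(L)
    com = table["com_frac"]

    L_th, L_cl, L_ua, L_fa, L_ha = (lengths[b] for b in SEGMENT_BASES)

    segments = [SegmentSpec("thorax", L_th, (0.0, 0.5 * L_th, 0.0))]
    joints = [
        JointConstraint(
            "ground_thorax",
            None,
            "thorax",
            ("flex_ext", "abd_add", "int_ext"),
            ("x", "y", "z"),
            (0.0, 0.0, 0.0),
        )
    ]
    markers: dict[str, tuple[str, np.ndarray]] = {
        "SJN": ("thorax", np.array([0.05, 0.95 * L_th, 0.0])),
        "SXS": ("thorax", np.array([0.07, 0.55 * L_th, 0.0])),
        "C7": ("thorax", np.array([-0.06, L_th, 0.0])),
        "T8": ("thorax", np.array([-0.08, 0.55 * L_th, 0.0])),
        "T12": ("thorax", np.array([-0.08, 0.12 * L_th, 0.0])),
    }

    for side in SIDES:
        lat = 1.0 if side == "R" else -1.0
        cl, ua, fa, ha = (f"{b}_{side}" for b in SEGMENT_BASES[1:])
        segments += [
            SegmentSpec(cl, L_cl, (0.0, 0.0, lat * 0.5 * L_cl)),
            SegmentSpec(ua, L_ua, (0.0, -com["upper_arm"] * L_ua, 0.0)),
            SegmentSpec(fa, L_fa, (0.0, -com["forearm"] * L_fa, 0.0)),
            SegmentSpec(ha, L_ha, (0.0, -com["hand"] * L_ha, 0.0)),
        ]
        joints += [
            JointConstraint(
                f"sternoclavicular_{side}",
                "thorax",
                cl,
                ("abd_add", "int_ext"),
                (),
                (0.02, L_th, lat * 0.04),
            ),
            JointConstraint(
                f"shoulder_{side}",
                cl,
                ua,
                ("flex_ext", "abd_add", "int_ext"),
                (),
                (0.0, 0.0, lat * L_cl),
            ),
            JointConstraint(
                f"elbow_{side}", ua, fa, ("flex_ext", "int_ext"), (), (0.0, -L_ua, 0.0)
            ),
            JointConstraint(
                f"wrist_{side}", fa, ha, ("flex_ext", "abd_add"), (), (0.0, -L_fa, 0.0)
            ),
        ]
        markers.update(
            {
                f"ACR_{side}": (cl, np.array([0.0, 0.03, lat * (L_cl + 0.01)])),
                f"HUM_{side}": (ua, np.array([0.03, -0.45 * L_ua, lat * 0.03])),
                f"EPL_{side}": (ua, np.array([0.0, -L_ua, lat * 0.045])),
                f"EPM_{side}": (ua, np.array([0.0, -L_ua, -lat * 0.045])),
                f"FRA_{side}": (fa, np.array([0.02, -0.45 * L_fa, lat * 0.025])),
                f"RSP_{side}": (fa, np.array([0.0, -L_fa, lat * 0.035])),
                f"USP_{side}": (fa, np.array([0.0, -L_fa, -lat * 0.035])),
                f"HND_{side}": (ha, np.array([0.02, -0.55 * L_ha, 0.0])),
            }
        )

    extra = {
        "cervical": ("thorax", np.array([0.0, L_th, 0.0])),
        "thoracic": ("thorax", np.array([0.0, 0.0, 0.0])),
        "lumbar": ("thorax", np.array([0.0, -0.06, 0.0])),
    }
    return KinematicChain(segments, joints, markers, extra, profile)


# ---------------------------------------------------------------------------
# forward kinematics


def _fk_array(chain: KinematicChain, q: np.ndarray) -> np.ndarray:
    """Poses for all segments, shape (n_segments, 4, 4)."""
    q = np.asarray(q, dtype=float)
    if q.shape != (chain.n_q,):
        raise ValueError(f"q has length {q.shape}, chain expects ({chain.n_q},)")
    S = len(chain.segments)
    R = np.empty((S, 3, 3))
    t = np.empty((S, 3))
    Rr = np.eye(3)
    for idx, ax in chain._root_rot:
        Rr = Rr @ _axis_rot(ax, q[idx])
    R[0] = Rr
    t[0] = q[chain._root_trans] if chain._root_trans else np.zeros(3)
    for pidx, cidx, offset, rots in chain._fk_joints:
        Rj = np.eye(3)
        for idx, ax in rots:
            Rj = Rj @ _axis_rot(ax, q[idx])
        R[cidx] = R[pidx] @ Rj
        t[cidx] = R[pidx] @ offset + t[pidx]
    T = np.zeros((S, 4, 4))
    T[:, :3, :3] = R
    T[:, :3, 3] = t
    T[:, 3, 3] = 1.0
    return T


def forward_kinematics(chain: KinematicChain, q: np.ndarray) -> dict[str, np.ndarray]:
    """Map each segment name to its 4x4 global pose for coordinates q."""
    T = _fk_array(chain, q)
    return {name: T[i] for i, name in enumerate(chain.segment_names)}


def marker_positions(chain: KinematicChain, q: np.ndarray) -> np.ndarray:
    """Model-predicted marker positions m_i(q), shape (n_markers, 3)."""
    T = _fk_array(chain, q)
    R = T[chain._marker_seg, :3, :3]
    t = T[chain._marker_seg, :3, 3]
    return np.einsum("mij,mj->mi", R, chain._marker_local) + t


def marker_jacobian(chain: KinematicChain, q: np.ndarray) -> np.ndarray:
    """Analytic d(marker positions)/dq, shape (n_markers, 3, n_q).

    Geometric chain Jacobian: a rotational DoF with global axis a acting
    about joint center c moves a downstream point p by a x (p - c); root
    translations move every point identically.
    """
    q = np.asarray(q, dtype=float)
    T = _fk_array(chain, q)
    S = len(chain.segments)
    R = T[:, :3, :3]
    t = T[:, :3, 3]

    # per non-root joint: center and global axis per free rotation
    n_joints = len(chain._fk_joints)
    jc = np.empty((n_joints, 3))
    jaxes: list[list[tuple[int, np.ndarray]]] = []
    unit = {"x": np.array([1.0, 0.0, 0.0]), "y": np.array([0.0, 1.0, 0.0]), "z": np.array([0.0, 0.0, 1.0])}
    for jn, (pidx, cidx, offset, rots) in enumerate(chain._fk_joints):
        c = R[pidx] @ offset + t[pidx]
        jc[jn] = c
        Racc = R[pidx].copy()
        axes = []
        for idx, ax in rots:
            axes.append((idx, Racc @ unit[ax]))
            Racc = Racc @ _axis_rot(ax, q[idx])
        jaxes.append(axes)
    # root rotation axes (about root origin t[0])
    root_axes = []
    Racc = np.eye(3)
    for idx, ax in chain._root_rot:
        root_axes.append((idx, Racc @ unit[ax]))
        Racc = Racc @ _axis_rot(ax, q[idx])

    P = np.einsum("mij,mj->mi", R[chain._marker_seg], chain._marker_local) + t[chain._marker_seg]
    M = P.shape[0]
    J = np.zeros((M, 3, chain.n_q))
    for m in range(M):
        p = P[m]
        for k, idx in enumerate(chain._root_trans):
            J[m, k, idx] = 1.0  # identity columns for root translation
        for idx, a in root_axes:
            J[m, :, idx] = np.cross(a, p - t[0])
        for jn in chain._ancestor_joints[chain._marker_seg[m]]:
            for idx, a in jaxes[jn]:
                J[m, :, idx] = np.cross(a, p - jc[jn])
    return J


def joint_centers(
    poses: Mapping[str, np.ndarray], chain: KinematicChain
) -> dict[str, np.ndarray]:
    """Global joint-center positions from segment poses.

    Sternoclavicular, shoulder, elbow and wrist centers are fixed points of
    the proximal segment frame (elbow/wrist stored as epicondyle/styloid
    midpoints); cervical/thoracic/lumbar centers are regression-style points
    stored in the thorax frame.
    """
    out: dict[str, np.ndarray] = {}
    for j in chain.joints[1:]:
        if j.parent not in poses:
            raise ValueError(f"missing pose for segment {j.parent!r} required by joint {j.name!r}")
        T = np.asarray(poses[j.parent])
        out[j.name] = T[:3, :3] @ j.offset_in_parent + T[:3, 3]
    for name, (seg, local) in chain.extra_joint_centers.items():
        if seg not in poses:
            raise ValueError(f"missing pose for segment {seg!r} required by joint {name!r}")
        T = np.asarray(poses[seg])
        out[name] = T[:3, :3] @ local + T[:3, 3]
    return out


def project_markers(
    chain: KinematicChain, poses: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Global marker positions for one frame of segment poses."""
    out: dict[str, np.ndarray] = {}
    for lab, (seg, local) in chain.marker_local_positions.items():
        if seg not in poses:
            raise ValueError(f"missing pose for segment {seg!r} carrying marker {lab!r}")
        T = np.asarray(poses[seg])
        out[lab] = T[:3, :3] @ local + T[:3, 3]
    return out


# ---------------------------------------------------------------------------
# subject-specific scaling

#: per segment, the marker pair whose midpoint defines the distal joint center
_DISTAL_PAIRS = {"upper_arm": ("EPL", "EPM"), "forearm": ("RSP", "USP")}


def scale_template(chain: KinematicChain, static_frame) -> KinematicChain:
    """Adapt the generic template to a static capture of the subject.

    Fits the chain to the (time-averaged) static marker cloud, re-derives
    every marker's local position in its fitted segment frame, and replaces
    the elbow/wrist joint-center offsets by the measured epicondyle/styloid
    midpoints (segment lengths follow). Placement idiosyncrasies of the
    subject's markers are thereby absorbed into the model, as in routine
    model scaling.
    """
    from .containers import MarkerTrajectories
    from .mko import WeightScheme, solve_frame, static_initializer

    if isinstance(static_frame, MarkerTrajectories):
        if static_frame.n_frames == 0:
            raise ValueError("static frame is empty")
        positions = {
            lab: np.nanmean(static_frame.data[:, j, :], axis=0)
            for j, lab in enumerate(static_frame.labels)
        }
    else:
        positions = {k: np.asarray(v, dtype=float) for k, v in dict(static_frame).items()}

    missing = [m for m in chain.marker_labels if m not in positions or not np.all(np.isfinite(positions[m]))]
    if missing:
        raise ValueError(f"static frame is missing landmark markers: {missing}")

    scaled = chain.copy()
    weights = WeightScheme.default()
    q = static_initializer(scaled)

    def _measured_origins(poses):
        """Fitted origins, with forearm/hand moved onto measured midpoints."""
        origin = {seg: poses[seg][:3, 3].copy() for seg in scaled.segment_names}
        for side in SIDES:
            origin[f"forearm_{side}"] = 0.5 * (positions[f"EPL_{side}"] + positions[f"EPM_{side}"])
            origin[f"hand_{side}"] = 0.5 * (positions[f"RSP_{side}"] + positions[f"USP_{side}"])
        return origin

    def _update_geometry(poses, origin):
        """Re-derive elbow/wrist offsets and arm lengths from the fit."""
        ratios = {}
        for side in SIDES:
            for joint, parent, child in (
                (f"elbow_{side}", f"upper_arm_{side}", f"forearm_{side}"),
                (f"wrist_{side}", f"forearm_{side}", f"hand_{side}"),
            ):
                Rp = poses[parent][:3, :3]
                offset = Rp.T @ (origin[child] - origin[parent])
                scaled.joint(joint).offset_in_parent = offset
                new_len = float(np.linalg.norm(offset))
                sspec = scaled.segment(parent)
                ratios[parent] = new_len / sspec.length
                sspec.com_offset = sspec.com_offset * ratios[parent]
                sspec.length = new_len
        return ratios

    # iterate length estimation with template-shaped marker locals: the arm
    # lengths and the fitted shoulder position co-adapt until consistent
    for _pass in range(20):
        q, _rep = solve_frame(scaled, positions, weights, q, xtol=1e-14, ftol=1e-14, gtol=1e-12)
        poses = forward_kinematics(scaled, q)
        ratios = _update_geometry(poses, _measured_origins(poses))
        for lab, (seg, pos) in scaled.marker_local_positions.items():
            if seg in ratios:  # long-axis coordinate scales with the length
                pos = pos * np.array([1.0, ratios[seg], 1.0])
            scaled.marker_local_positions[lab] = (seg, pos)
        scaled._finalize()
        if max(abs(r - 1.0) for r in ratios.values()) < 1e-5:
            break

    # final pass: absorb the measured marker cloud into the segment frames
    q, _rep = solve_frame(scaled, positions, weights, q, xtol=1e-14, ftol=1e-14, gtol=1e-12)
    poses = forward_kinematics(scaled, q)
    origin = _measured_origins(poses)
    local = {}
    for lab, (seg, _old) in scaled.marker_local_positions.items():
        R = poses[seg][:3, :3]
        local[lab] = (seg, R.T @ (positions[lab] - origin[seg]))
    scaled.marker_local_positions = local
    _update_geometry(poses, origin)
    scaled._finalize()
    return scaled
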