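"""Synthetic boxing motion with known ground truth.

Generates shadow-boxing-like joint trajectories on the upper-limb chain
(guard posture, footwork sway, minimum-jerk punch extensions whose
amplitude is calibrated so the hand-CoM peak speed matches the script),
renders noise-free markers by forward kinematics, corrupts them with a
soft-tissue-artifact-like noise model, and emulates a second, lower-rate
measurement stream of segment poses with injected per-axis biases.

Every stream is reproducible bit-for-bit under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal

from .containers import MarkerTrajectories, PoseStream, QTrajectory
from .model import KinematicChain, _fk_array

PUNCH_TYPES = (
    "direct_face",
    "direct_body",
    "double_direct",
    "jab_hook",
    "uppercut_hook_hook",
)

#: default soft-tissue-artifact RMS per segment base (m); free parameters of
#: the corruption model, order-of-magnitude of skin-marker artifact reports
DEFAULT_STA_AMPLITUDE = {
    "thorax": 0.005,
    "clavicle": 0.005,
    "upper_arm": 0.010,
    "forearm": 0.010,
    "hand": 0.010,
}


@dataclass
class PunchScript:
    """One shadow-boxing trial: punch type, arm, repetitions and pacing."""

    punch_type: str = "direct_face"
    side: str = "front"
    repetitions: int = 4
    peak_hand_speed: float = 7.5  # m/s, front-hand peak of the punching arm
    duration_per_punch: float = 0.6  # s per punch event (extend + retract)
    guard_posture: np.ndarray | None = None
    inter_punch_dwell: float = 0.7  # s of guard/footwork between repetitions
    lead_in: float = 0.5  # s of guard before the first punch

    def __post_init__(self) -> None:
        if self.punch_type not in PUNCH_TYPES:
            raise ValueError(f"unknown punch type {self.punch_type!r}")
        if self.side not in ("front", "rear"):
            raise ValueError("side must be 'front' or 'rear'")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.peak_hand_speed < 0:
            raise ValueError("peak_hand_speed must be >= 0")
        if self.duration_per_punch <= 0:
            raise ValueError("duration_per_punch must be positive")


@dataclass
class CorruptionModel:
    """Marker corruption: placement offset + band-limited STA + white jitter."""

    sta_amplitude: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STA_AMPLITUDE)
    )
    sta_bandwidth: float = 3.0  # Hz
    jitter_sd: float = 0.0005  # m, per coordinate
    placement_offset_sd: float = 0.005  # m, per coordinate, constant in time
    seed: int = 0

    def __post_init__(self) -> None:
        amps = (
            self.sta_amplitude.values()
            if isinstance(self.sta_amplitude, Mapping)
            else [self.sta_amplitude]
        )
        if any(a < 0 for a in amps) or min(self.sta_bandwidth, 0) < 0:
            raise ValueError("corruption parameters must be non-negative")
        if self.jitter_sd < 0 or self.placement_offset_sd < 0:
            raise ValueError("corruption parameters must be non-negative")

    @classmethod
    def none(cls, seed: int = 0) -> "CorruptionModel":
        return cls(sta_amplitude=0.0, jitter_sd=0.0, placement_offset_sd=0.0, seed=seed)


@dataclass
class SystemEmulation:
    """Emulated markerless export: rate, per-axis angle biases, pose noise.

    ``angle_bias`` maps (joint name, DoF label) to a radian offset added to
    that generalized coordinate before forward kinematics; noise is applied
    in coordinate space so pose matrices stay valid rigid transforms.
    ``joint_center_offset`` translates a joint's proximal-segment pose,
    shifting that joint's reported center without touching any angle.
    """

    angle_bias: dict[tuple[str, str], float] = field(default_factory=dict)
    pose_noise_rot_sd: float = 0.0  # rad
    pose_noise_trans_sd: float = 0.0  # m
    rate: float = 60.0  # Hz
    joint_center_offset: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")


# ---------------------------------------------------------------------------
# punch choreography


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 6 * tau**5 - 15 * tau**4 + 10 * tau**3


def guard_posture(chain: KinematicChain) -> np.ndarray:
    """Defensive guard: elbows flexed in front of the body, slight abduction."""
    q = chain.q_zero()
    for side in ("L", "R"):
        lat = 1.0 if side == "R" else -1.0
        q[chain.q_index[(f"shoulder_{side}", "flex_ext")]] = 0.5
        q[chain.q_index[(f"shoulder_{side}", "abd_add")]] = -lat * 0.26
        q[chain.q_index[(f"elbow_{side}", "flex_ext")]] = 2.10
    return q


def _punch_target(chain: KinematicChain, side: str, variant: str) -> dict[int, float]:
    """Target arm/root coordinates (absolute values) for one punch variant."""
    lat = 1.0 if side == "R" else -1.0
    qi = chain.q_index
    t: dict[int, float] = {}

    def set_(joint: str, dof: str, val: float) -> None:
        t[qi[(f"{joint}_{side}", dof)]] = val

    if variant in ("straight_high", "straight_low"):
        set_("sternoclavicular", "abd_add", -lat * 0.18)
        set_("sternoclavicular", "int_ext", lat * 0.35)
        set_("shoulder", "flex_ext", 1.90 if variant == "straight_high" else 1.30)
        set_("shoulder", "abd_add", -lat * 0.12)
        set_("shoulder", "int_ext", lat * 0.35)
        set_("elbow", "flex_ext", 0.08 if variant == "straight_high" else 0.22)
        set_("elbow", "int_ext", lat * 0.40)
        set_("wrist", "flex_ext", -0.45)
        t[qi[("ground_thorax", "tx")]] = 0.45
        t[qi[("ground_thorax", "int_ext")]] = lat * 0.50
    elif variant in ("hook_high", "hook_low"):
        set_("sternoclavicular", "abd_add", -lat * 0.10)
        set_("shoulder", "flex_ext", 1.2 if variant == "hook_high" else 0.9)
        set_("shoulder", "abd_add", -lat * 1.30)
        set_("shoulder", "int_ext", lat * 0.70)
        set_("elbow", "flex_ext", 1.20)
        t[qi[("ground_thorax", "tx")]] = 0.25
        t[qi[("ground_thorax", "int_ext")]] = lat * 0.80
    elif variant == "uppercut":
        set_("sternoclavicular", "abd_add", -lat * 0.10)
        set_("shoulder", "flex_ext", 1.3)
        set_("shoulder", "abd_add", -lat * 0.15)
        set_("elbow", "flex_ext", 2.30)
        t[qi[("ground_thorax", "tx")]] = 0.30
        t[qi[("ground_thorax", "ty")]] = 0.12
    else:
        raise ValueError(f"unknown punch variant {variant!r}")
    return t


_COMBOS = {
    "direct_face": (("primary", "straight_high"),),
    "direct_body": (("primary", "straight_low"),),
    "double_direct": (("primary", "straight_high"), ("primary", "straight_high")),
    "jab_hook": (("primary", "straight_high"), ("other", "hook_high")),
    "uppercut_hook_hook": (
        ("primary", "uppercut"),
        ("primary", "hook_low"),
        ("primary", "hook_high"),
    ),
}

_EXTEND_FRAC = 0.40
_RETRACT_FRAC = 0.45


def _assemble(
    chain: KinematicChain,
    script: PunchScript,
    rate: float,
    scale: float,
    events: list[tuple[float, str, str]],
    total_time: float,
    sway_phases: np.ndarray,
    amp_jitter: np.ndarray,
) -> np.ndarray:
    n = int(round(total_time * rate)) + 1
    t = np.arange(n) / rate
    q_guard = script.guard_posture if script.guard_posture is not None else guard_posture(chain)
    Q = np.tile(q_guard, (n, 1))

    D = script.duration_per_punch
    for p, (t0, side, variant) in enumerate(events):
        target = _punch_target(chain, side, variant)
        a = scale * (1.0 + amp_jitter[p])
        rise = _minimum_jerk((t - t0) / (_EXTEND_FRAC * D))
        fall = _minimum_jerk((t - t0 - _EXTEND_FRAC * D) / (_RETRACT_FRAC * D))
        env = np.where(t < t0, 0.0, rise - fall)
        for idx, val in target.items():
            Q[:, idx] += a * (val - q_guard[idx]) * env

    # footwork sway (root oscillation, ~0-1 m/s) present throughout
    p1, p2, p3, p4 = sway_phases
    qi = chain.q_index
    Q[:, qi[("ground_thorax", "tx")]] += 0.10 * np.sin(2 * np.pi * 0.9 * t + p1)
    Q[:, qi[("ground_thorax", "tz")]] += 0.08 * np.sin(2 * np.pi * 0.7 * t + p2)
    Q[:, qi[("ground_thorax", "ty")]] += 0.015 * np.sin(2 * np.pi * 1.8 * t + p3)
    Q[:, qi[("ground_thorax", "int_ext")]] += 0.05 * np.sin(2 * np.pi * 0.5 * t + p4)
    return Q


def _hand_peak_speed(chain: KinematicChain, Q: np.ndarray, rate: float, side: str) -> float:
    hand = chain.segment(f"hand_{side}")
    hand_idx = chain._seg_index[hand.name]
    T = np.empty((len(Q), 3))
    for k in range(len(Q)):
        pose = _fk_array(chain, Q[k])[hand_idx]
        T[k] = pose[:3, :3] @ hand.com_offset + pose[:3, 3]
    v = np.linalg.norm(np.gradient(T, 1.0 / rate, axis=0), axis=1)
    return float(np.max(v))


def generate_q_trajectory(
    chain: KinematicChain,
    script: PunchScript,
    rate: float = 300.0,
    seed: int = 0,
    front_side: str = "L",
) -> QTrajectory:
    """Ground-truth coordinates for one shadow-boxing trial.

    C2-smooth minimum-jerk punch extensions alternate with guard posture and
    footwork sway; the punch amplitude is calibrated numerically so the
    punching hand's CoM peak speed matches ``script.peak_hand_speed`` within
    2 %. Raises when the requested speed is outside the attainable range,
    reporting the attainable bound.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if front_side not in ("L", "R"):
        raise ValueError("front_side must be 'L' or 'R'")
    rng = np.random.default_rng([seed, 17])
    primary = front_side if script.side == "front" else ("R" if front_side == "L" else "L")
    other = "R" if primary == "L" else "L"

    combo = _COMBOS[script.punch_type]
    # event schedule
    events: list[tuple[float, str, str]] = []
    t_cursor = script.lead_in
    dwell_jit = 1.0 + 0.15 * rng.uniform(-1, 1, size=script.repetitions)
    for r in range(script.repetitions):
        for who, variant in combo:
            side = primary if who == "primary" else other
            events.append((t_cursor, side, variant))
            t_cursor += script.duration_per_punch
        t_cursor += script.inter_punch_dwell * dwell_jit[r]
    total_time = t_cursor + 0.4
    sway_phases = rng.uniform(0, 2 * np.pi, size=4)
    amp_jitter = np.clip(rng.normal(0.0, 0.02, size=len(events)), -0.05, 0.05)

    def build(scale: float) -> np.ndarray:
        return _assemble(chain, script, rate, scale, events, total_time, sway_phases, amp_jitter)

    target = script.peak_hand_speed
    if target == 0.0:
        return QTrajectory(build(0.0), rate)

    g_cap = 1.0 / (1.0 + float(np.max(amp_jitter)))
    v_cap = _hand_peak_speed(chain, build(g_cap), rate, primary)
    v_floor = _hand_peak_speed(chain, build(0.0), rate, primary)
    if target > v_cap or target < v_floor:
        raise ValueError(
            f"peak hand speed {target:.2f} m/s unattainable for this script; "
            f"attainable range is [{v_floor:.2f}, {v_cap:.2f}] m/s"
        )
    g = min(g_cap, g_cap * target / v_cap)
    for _ in range(10):
        v = _hand_peak_speed(chain, build(g), rate, primary)
        if abs(v / target - 1.0) < 0.005:
            break
        g = min(g_cap, g * target / v)
    return QTrajectory(build(g), rate)


# ---------------------------------------------------------------------------
# measurement emulation


def render_markers(
    chain: KinematicChain, q_traj: QTrajectory, rate: float | None = None
) -> MarkerTrajectories:
    """Noise-free marker trajectories by frame-wise forward kinematics."""
    if rate is not None and rate != q_traj.rate:
        raise ValueError("render rate must match the trajectory rate")
    T = q_traj.n_frames
    M = len(chain.marker_labels)
    data = np.empty((T, M, 3))
    for k in range(T):
        fk = _fk_array(chain, q_traj.q[k])
        R = fk[chain._marker_seg, :3, :3]
        t = fk[chain._marker_seg, :3, 3]
        data[k] = np.einsum("mij,mj->mi", R, chain._marker_local) + t
    return MarkerTrajectories(list(chain.marker_labels), data, q_traj.rate)


def _sta_amplitude_vector(
    model: CorruptionModel, markers: MarkerTrajectories, chain: KinematicChain | None
) -> np.ndarray:
    if not isinstance(model.sta_amplitude, Mapping):
        return np.full(len(markers.labels), float(model.sta_amplitude))
    if chain is None:
        raise ValueError("per-segment sta_amplitude requires the chain argument")
    amps = np.empty(len(markers.labels))
    for i, lab in enumerate(markers.labels):
        seg = chain.marker_local_positions[lab][0]
        base = seg.rsplit("_", 1)[0] if seg != "thorax" else "thorax"
        amps[i] = model.sta_amplitude.get(base, 0.0)
    return amps


def corrupt_markers(
    markers: MarkerTrajectories,
    model: CorruptionModel,
    chain: KinematicChain | None = None,
    noise_seed: int | None = None,
) -> MarkerTrajectories:
    """Apply placement offsets, band-limited STA and white jitter.

    Placement offsets are constant in time and drawn only from the model
    seed and the marker order, so a static and a dynamic capture corrupted
    with the same model share the same (subject-specific) placement error.
    ``noise_seed`` re-seeds only the time-varying terms (STA, jitter) so
    different trials of one subject get fresh artifact while keeping the
    placement identical; it defaults to the model seed.
    """
    out = markers.copy()
    T, M, _ = out.data.shape
    nseed = model.seed if noise_seed is None else noise_seed

    if model.placement_offset_sd > 0:
        rng_p = np.random.default_rng([model.seed, 1])
        out.data += rng_p.normal(0.0, model.placement_offset_sd, size=(M, 3))[None]

    amps = _sta_amplitude_vector(model, markers, chain)
    if np.any(amps > 0) and T >= 2:
        rng_s = np.random.default_rng([nseed, 2])
        white = rng_s.standard_normal((T, M, 3))
        if model.sta_bandwidth <= 0 or model.sta_bandwidth >= markers.rate / 2:
            sta = white
        else:
            b, a = signal.butter(2, model.sta_bandwidth, btype="low", fs=markers.rate)
            padlen = min(T - 1, 3 * (max(len(a), len(b)) - 1))
            sta = signal.filtfilt(b, a, white, axis=0, padlen=padlen)
        rms = np.sqrt(np.mean(np.sum(sta**2, axis=2), axis=0))  # per-marker vector RMS
        sta = sta / np.where(rms > 0, rms, 1.0)[None, :, None] * amps[None, :, None]
        out.data += sta

    if model.jitter_sd > 0:
        rng_j = np.random.default_rng([nseed, 3])
        out.data += rng_j.normal(0.0, model.jitter_sd, size=(T, M, 3))
    return out


def resample_q(q_traj: QTrajectory, rate_out: float) -> QTrajectory:
    """Resample coordinates onto the target rate's timestamps.

    Integer decimation picks exact source samples; otherwise linear
    interpolation in time.
    """
    if rate_out == q_traj.rate:
        return q_traj.copy()
    if rate_out > q_traj.rate:
        raise ValueError("emulated rate cannot exceed the source rate")
    step = q_traj.rate / rate_out
    if abs(step - round(step)) < 1e-9:
        q = q_traj.q[:: int(round(step))].copy()
    else:
        t_in = q_traj.time
        n_out = int(np.floor(t_in[-1] * rate_out)) + 1
        t_out = np.arange(n_out) / rate_out
        q = np.column_stack(
            [np.interp(t_out, t_in, q_traj.q[:, j]) for j in range(q_traj.n_q)]
        )
    return QTrajectory(q, rate_out)


def emulate_markerless(
    chain: KinematicChain,
    q_traj: QTrajectory,
    emu: SystemEmulation,
    seed: int = 0,
) -> PoseStream:
    """Emulated markerless pose export at ``emu.rate``.

    Resamples the true coordinates, injects per-axis angle biases and
    Gaussian coordinate noise, runs forward kinematics, then applies any
    joint-center translation offsets. All output poses are valid rigid
    transforms because perturbations act in coordinate space.
    """
    q_low = resample_q(q_traj, emu.rate)
    q = q_low.q.copy()
    for (joint, dof), bias in emu.angle_bias.items():
        key = (joint, dof)
        if key not in chain.q_index:
            raise ValueError(f"angle_bias names unknown DoF {key}")
        q[:, chain.q_index[key]] += bias
    if emu.pose_noise_rot_sd > 0 or emu.pose_noise_trans_sd > 0:
        rng = np.random.default_rng([seed, 5])
        trans_idx = set(chain._root_trans)
        sds = np.array(
            [
                emu.pose_noise_trans_sd if j in trans_idx else emu.pose_noise_rot_sd
                for j in range(chain.n_q)
            ]
        )
        q += rng.standard_normal(q.shape) * sds[None, :]

    T = len(q)
    data = np.empty((T, len(chain.segments), 4, 4))
    for k in range(T):
        data[k] = _fk_array(chain, q[k])
    for joint, offset in emu.joint_center_offset.items():
        seg = chain.joint(joint).parent
        data[:, chain._seg_index[seg], :3, 3] += np.asarray(offset, dtype=float)
    return PoseStream(list(chain.segment_names), data, emu.rate)
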