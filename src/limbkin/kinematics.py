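"""Kinematic variables from pose streams.

Cardan joint angles, joint-center distances between two measurement
streams, segment centre-of-mass speeds, zero-phase Butterworth filtering,
and rate alignment of the 300 Hz marker stream onto the 60 Hz video stream.

Angles are radians internally; reporting converts to degrees. The default
cardan sequence is intrinsic Z-X-Y = (flexion/extension,
abduction/adduction, internal/external rotation); on the left side the
second and third components are sign-mirrored at extraction so that
flexion, abduction and internal rotation are positive on both sides.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .containers import PoseStream
from .model import KinematicChain, check_pose, joint_centers

#: axis labels in sequence order for the default Z-X-Y decomposition
AXIS_LABELS = ("flex_ext", "abd_add", "int_ext")

#: locked joint axes, absent from all reports
LOCKED_AXES = {("elbow", "abd_add"), ("wrist", "int_ext")}

#: extraction pairs: joint base -> (parent segment base, child segment base)
ANGLE_PAIRS = {
    "shoulder": ("thorax", "upper_arm"),
    "elbow": ("upper_arm", "forearm"),
    "wrist": ("forearm", "hand"),
}

GIMBAL_MARGIN = np.deg2rad(1.0)


@dataclass
class FilterSpec:
    """Low-pass Butterworth specification (applied forward-backward)."""

    order: int = 4
    cutoff: float = 8.0  # Hz
    zero_phase: bool = True

    def validate(self, rate: float) -> None:
        if not self.cutoff < rate / 2:
            raise ValueError(f"cutoff {self.cutoff} Hz must be below Nyquist {rate / 2} Hz")


def cardan_angles(
    parent: np.ndarray, child: np.ndarray, sequence: str = "ZXY"
) -> tuple[np.ndarray, bool]:
    """Decompose the relative parent->child rotation into cardan angles.

    Returns (angles in sequence order [rad], gimbal_flag); the flag is True
    when the middle angle is within 1 degree of +/-90 degrees, where the
    first and third axes align and the decomposition degenerates.
    """
    parent = np.asarray(parent, dtype=float)
    child = np.asarray(child, dtype=float)
    check_pose(parent, tol=1e-6)
    check_pose(child, tol=1e-6)
    R_rel = parent[:3, :3].T @ child[:3, :3]
    angles = Rotation.from_matrix(R_rel).as_euler(sequence)
    gimbal = bool(abs(abs(angles[1]) - np.pi / 2) < GIMBAL_MARGIN)
    return angles, gimbal


def _relative_angles_series(
    stream: PoseStream, parent: str, child: str, sequence: str
) -> tuple[np.ndarray, np.ndarray]:
    ip, ic = stream.segments.index(parent), stream.segments.index(child)
    Rp = stream.data[:, ip, :3, :3]
    Rc = stream.data[:, ic, :3, :3]
    ok = np.all(np.isfinite(Rp.reshape(len(Rp), -1)), axis=1) & np.all(
        np.isfinite(Rc.reshape(len(Rc), -1)), axis=1
    )
    out = np.full((stream.n_frames, 3), np.nan)
    if np.any(ok):
        R_rel = np.einsum("tji,tjk->tik", Rp[ok], Rc[ok])
        out[ok] = Rotation.from_matrix(R_rel).as_euler(sequence)
    gimbal = np.abs(np.abs(out[:, 1]) - np.pi / 2) < GIMBAL_MARGIN
    return out, gimbal


def joint_angle_series(
    stream: PoseStream,
    chain: KinematicChain,
    sequence: str = "ZXY",
    mirror_left: bool = True,
) -> dict[tuple[str, str], np.ndarray]:
    """Angles for shoulder/elbow/wrist per side, shape (T, 3), radians.

    Keys are (joint base, side letter). Locked axes (elbow abd_add, wrist
    int_ext) are NaN-masked. Shoulder angles are taken between thorax and
    upper arm, spanning the sternoclavicular and glenohumeral rotations.
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    for joint, (pbase, cbase) in ANGLE_PAIRS.items():
        for side in ("L", "R"):
            parent = pbase if pbase == "thorax" else f"{pbase}_{side}"
            child = f"{cbase}_{side}"
            ang, _g = _relative_angles_series(stream, parent, child, sequence)
            if mirror_left and side == "L":
                ang = ang * np.array([1.0, -1.0, -1.0])
            for k, axis in enumerate(AXIS_LABELS):
                if (joint, axis) in LOCKED_AXES:
                    ang[:, k] = np.nan
            out[(joint, side)] = ang
    return out


def joint_center_series(
    stream: PoseStream, chain: KinematicChain
) -> dict[str, np.ndarray]:
    """Global joint-center positions over time, (T, 3) per joint."""
    out: dict[str, np.ndarray] = {}
    for j in chain.joints[1:]:
        i = stream.segments.index(j.parent)
        R = stream.data[:, i, :3, :3]
        t = stream.data[:, i, :3, 3]
        out[j.name] = np.einsum("tij,j->ti", R, j.offset_in_parent) + t
    for name, (seg, local) in chain.extra_joint_centers.items():
        i = stream.segments.index(seg)
        R = stream.data[:, i, :3, :3]
        t = stream.data[:, i, :3, 3]
        out[name] = np.einsum("tij,j->ti", R, local) + t
    return out


def joint_center_distance(
    stream_a: PoseStream, stream_b: PoseStream, chain: KinematicChain,
    chain_b: KinematicChain | None = None,
) -> dict[str, np.ndarray]:
    """Per-frame 3D distances between corresponding joint centers (m).

    Streams must already be time-aligned and of equal length (use
    ``resample_align`` on the higher-rate stream first). ``chain_b`` allows
    the second stream to carry its own geometry (e.g. the video system's
    model); it defaults to ``chain``.
    """
    if stream_a.n_frames != stream_b.n_frames:
        raise ValueError(
            "streams have different lengths "
            f"({stream_a.n_frames} vs {stream_b.n_frames}); resample_align first"
        )
    chain_b = chain_b or chain
    names = [j.name for j in chain.joints[1:] if j.name.split("_")[0] in ANGLE_PAIRS]
    out = {n: np.full(stream_a.n_frames, np.nan) for n in names}
    for k in range(stream_a.n_frames):
        fa, fb = stream_a.frame(k), stream_b.frame(k)
        if any(not np.all(np.isfinite(v)) for v in fa.values()):
            continue
        if any(not np.all(np.isfinite(v)) for v in fb.values()):
            continue
        ca = joint_centers(fa, chain)
        cb = joint_centers(fb, chain_b)
        for n in names:
            out[n][k] = float(np.linalg.norm(ca[n] - cb[n]))
    return out


def com_positions(stream: PoseStream, chain: KinematicChain) -> dict[str, np.ndarray]:
    """Global segment CoM positions, (T, 3) per segment."""
    out = {}
    for seg in chain.segments:
        i = stream.segments.index(seg.name)
        R = stream.data[:, i, :3, :3]
        t = stream.data[:, i, :3, 3]
        out[seg.name] = np.einsum("tij,j->ti", R, seg.com_offset) + t
    return out


def com_speed(stream: PoseStream, chain: KinematicChain) -> dict[str, np.ndarray]:
    """Segment CoM speed magnitude (m/s) by central finite differences.

    One-sided differences at the trial ends; requires >= 3 frames.
    """
    if stream.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    if stream.rate is None or stream.rate <= 0:
        raise ValueError("pose stream carries no sampling rate")
    dt = 1.0 / stream.rate
    pos = com_positions(stream, chain)
    return {
        seg: np.linalg.norm(np.gradient(p, dt, axis=0), axis=1) for seg, p in pos.items()
    }


def butterworth(series: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Zero-phase low-pass Butterworth filtering along axis 0.

    The filter is applied forward-backward (zero phase, squared magnitude:
    -6 dB at the cutoff) with reflective padding. NaN-masked gaps split the
    signal and each finite run is filtered on its own; runs shorter than
    the padding are rejected.
    """
    spec.validate(rate)
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    b, a = signal.butter(spec.order, spec.cutoff, btype="low", fs=rate)
    # reflective padding of at least three filter time constants
    padlen = max(3 * (max(len(a), len(b)) - 1), int(np.ceil(3 * rate / (2 * np.pi * spec.cutoff))))
    out = np.full_like(x, np.nan)
    for col in range(x.shape[1]):
        finite = np.isfinite(x[:, col])
        if not finite.any():
            continue
        edges = np.flatnonzero(np.diff(finite.astype(int)))
        starts = np.r_[0, edges + 1]
        stops = np.r_[edges, len(finite) - 1] + 1
        for s, e in zip(starts, stops):
            if not finite[s]:
                continue
            run = x[s:e, col]
            if len(run) <= padlen:
                raise ValueError(
                    f"signal run of {len(run)} samples is shorter than the "
                    f"filter padding ({padlen} samples)"
                )
            if spec.zero_phase:
                out[s:e, col] = signal.filtfilt(b, a, run, padtype="even", padlen=padlen)
            else:
                out[s:e, col] = signal.lfilter(b, a, run)
    return out[:, 0] if squeeze else out


def resample_align(
    series: np.ndarray, rate_in: float, rate_out: float
) -> np.ndarray:
    """Anti-aliased resampling of a series onto the target rate's timestamps.

    Works for integer or rational rate ratios (polyphase filtering); output
    sample k sits at time k / rate_out. Identity when the rates match.
    """
    x = np.asarray(series, dtype=float)
    if rate_in == rate_out:
        return x.copy()
    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if abs(float(frac) - rate_out / rate_in) > 1e-9:
        raise ValueError(f"rate ratio {rate_out}/{rate_in} is not rational enough")
    return signal.resample_poly(x, up, down, axis=0, padtype="line")


def resample_pose_stream(stream: PoseStream, rate_out: float) -> PoseStream:
    """Decimate a pose stream by an integer factor (nearest-sample pick).

    Pose matrices cannot be low-pass filtered without leaving SO(3); the
    stream is subsampled onto the target timestamps instead. Derived scalar
    series (angles, positions, speeds) should be resampled with
    ``resample_align`` when anti-aliasing matters.
    """
    if stream.rate == rate_out:
        return stream.copy()
    step = stream.rate / rate_out
    if abs(step - round(step)) > 1e-9:
        raise ValueError("pose stream decimation requires an integer rate ratio")
    data = stream.data[:: int(round(step))]
    return PoseStream(list(stream.segments), data.copy(), rate_out)
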