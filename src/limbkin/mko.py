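"""Weighted multibody kinematic optimization (global inverse kinematics).

Each frame solves

    min_q  sum_i w_i * || m_i_measured - m_i_model(q) ||^2

over the chain's free coordinates only; locked DoFs never enter q, so the
joint constraints are satisfied exactly by construction. The solver is a
bounded trust-region nonlinear least squares (scipy ``least_squares``,
method ``trf``) with the analytic chain Jacobian.

Marker weights are segment-specific, ordered thorax > upper arm > forearm >
hand, and tunable by residual analysis over a calibration trial.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .containers import MarkerTrajectories, PoseStream, QTrajectory
from .model import KinematicChain, _fk_array, marker_jacobian, marker_positions

DEFAULT_SEGMENT_WEIGHTS = {
    "thorax": 10.0,
    "clavicle": 5.0,
    "upper_arm": 5.0,
    "forearm": 2.0,
    "hand": 1.0,
}

ELBOW_FLEXION_MAX = np.deg2rad(160.0)


@dataclass
class WeightScheme:
    """Per-marker weights w_i >= 0, grouped by segment base name."""

    segment_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_WEIGHTS)
    )
    marker_overrides: dict[str, float] = field(default_factory=dict)
    name: str = "default"

    def __post_init__(self) -> None:
        for k, w in {**self.segment_weights, **self.marker_overrides}.items():
            if w < 0:
                raise ValueError(f"negative weight for {k!r}")

    @classmethod
    def default(cls) -> "WeightScheme":
        return cls()

    def weight_for(self, label: str, segment: str) -> float:
        if label in self.marker_overrides:
            return self.marker_overrides[label]
        base = segment.rsplit("_", 1)[0] if segment != "thorax" else "thorax"
        return self.segment_weights.get(base, 1.0)

    def vector(self, chain: KinematicChain) -> np.ndarray:
        w = np.array(
            [
                self.weight_for(lab, chain.marker_local_positions[lab][0])
                for lab in chain.marker_labels
            ]
        )
        # every tracked segment needs at least one positive weight
        seg_idx = chain._marker_seg
        for s in np.unique(seg_idx):
            if not np.any(w[seg_idx == s] > 0):
                raise ValueError(
                    f"no positive marker weight on segment {chain.segment_names[s]!r}"
                )
        return w


@dataclass
class FrameReport:
    objective: float
    residual_norms: dict[str, float]
    iterations: int
    converged: bool


@dataclass
class SolveReport:
    """Per-frame objectives and residuals for a solved trajectory."""

    objective: np.ndarray  # (T,)
    residual_norms: np.ndarray  # (T, M), meters; NaN where marker missing
    iterations: np.ndarray  # (T,)
    converged: np.ndarray  # (T,) bool
    marker_labels: list[str]


def static_initializer(chain: KinematicChain) -> np.ndarray:
    """Anatomical posture with elbows at 90 deg guard flexion."""
    q = chain.q_zero()
    for side in ("L", "R"):
        q[chain.q_index[(f"elbow_{side}", "flex_ext")]] = np.pi / 2
    return q


def _bounds(chain: KinematicChain) -> tuple[np.ndarray, np.ndarray]:
    lo = np.full(chain.n_q, -np.pi)
    hi = np.full(chain.n_q, np.pi)
    root = chain.joints[0]
    for t in root.free_translations:
        i = chain.q_index[(root.name, "t" + t)]
        lo[i], hi[i] = -np.inf, np.inf
    for side in ("L", "R"):
        key = (f"elbow_{side}", "flex_ext")
        if key in chain.q_index:
            lo[chain.q_index[key]] = 0.0
            hi[chain.q_index[key]] = ELBOW_FLEXION_MAX
    return lo, hi


def _prepare_frame(
    chain: KinematicChain, markers: Mapping[str, np.ndarray] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Measured positions aligned to chain marker order + finite mask."""
    if isinstance(markers, np.ndarray):
        meas = np.asarray(markers, dtype=float)
        if meas.shape != (len(chain.marker_labels), 3):
            raise ValueError("marker array must be (n_markers, 3) in chain order")
    else:
        meas = np.full((len(chain.marker_labels), 3), np.nan)
        unknown = [k for k in markers if k not in chain.marker_labels]
        if unknown:
            warnings.warn(f"ignoring unlabeled markers: {unknown}")
        for i, lab in enumerate(chain.marker_labels):
            if lab in markers:
                meas[i] = np.asarray(markers[lab], dtype=float)
    mask = np.all(np.isfinite(meas), axis=1)
    return meas, mask


def _check_observable(chain: KinematicChain, meas: np.ndarray, mask: np.ndarray, w: np.ndarray) -> None:
    ok = mask & (w > 0)
    pts = meas[ok]
    if pts.shape[0] < 3:
        raise ValueError(f"need at least 3 weighted markers, got {pts.shape[0]}")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("weighted markers are collinear; pose is unobservable")


def solve_frame(
    chain: KinematicChain,
    markers: Mapping[str, np.ndarray] | np.ndarray,
    weights: WeightScheme | None = None,
    q_init: np.ndarray | None = None,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
    gtol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[np.ndarray, FrameReport]:
    """Fit q to one frame of measured markers (NaN markers are excluded)."""
    weights = weights or WeightScheme.default()
    q_init = chain.q_zero() if q_init is None else np.asarray(q_init, dtype=float)
    if q_init.shape != (chain.n_q,):
        raise ValueError("q_init length mismatch")
    w = weights.vector(chain)
    meas, mask = _prepare_frame(chain, markers)
    _check_observable(chain, meas, mask, w)
    idx = np.flatnonzero(mask & (w > 0))
    sw = np.sqrt(w[idx])[:, None]
    target = meas[idx]

    def fun(q: np.ndarray) -> np.ndarray:
        return (sw * (marker_positions(chain, q)[idx] - target)).ravel()

    def jac(q: np.ndarray) -> np.ndarray:
        J = marker_jacobian(chain, q)[idx]
        return (sw[:, :, None] * J).reshape(-1, chain.n_q)

    lo, hi = _bounds(chain)
    q0 = np.clip(q_init, lo + 1e-12, hi - 1e-12)
    res = least_squares(
        fun, q0, jac=jac, bounds=(lo, hi), method="trf",
        xtol=xtol, ftol=ftol, gtol=gtol, max_nfev=max_iter,
    )
    if res.status <= 0:
        warnings.warn("frame solve did not converge; returning best iterate")

    rnorm = np.full(len(chain.marker_labels), np.nan)
    final = marker_positions(chain, res.x)
    rnorm[mask] = np.linalg.norm(final[mask] - meas[mask], axis=1)
    objective = float(np.sum(w[idx] * rnorm[idx] ** 2))
    report = FrameReport(
        objective=objective,
        residual_norms=dict(zip(chain.marker_labels, rnorm)),
        iterations=int(res.nfev),
        converged=bool(res.status > 0),
    )
    return res.x, report


def solve_trajectory(
    chain: KinematicChain,
    markers: MarkerTrajectories,
    weights: WeightScheme | None = None,
    q_init: np.ndarray | None = None,
) -> tuple[QTrajectory, SolveReport]:
    """Frame-by-frame MKO with warm starts.

    Frame k starts from frame k-1's solution; frame 0 from the static guard
    initializer. Frames where too few markers are visible are flagged
    invalid (q row NaN), never interpolated.
    """
    weights = weights or WeightScheme.default()
    order = [markers.labels.index(lab) if lab in markers.labels else -1
             for lab in chain.marker_labels]
    missing_all = [lab for lab, o in zip(chain.marker_labels, order) if o < 0]
    if missing_all:
        warnings.warn(f"markers never observed: {missing_all}")

    T = markers.n_frames
    Q = np.full((T, chain.n_q), np.nan)
    valid = np.zeros(T, dtype=bool)
    obj = np.full(T, np.nan)
    rnorms = np.full((T, len(chain.marker_labels)), np.nan)
    iters = np.zeros(T, dtype=int)
    conv = np.zeros(T, dtype=bool)

    q_prev = static_initializer(chain) if q_init is None else np.asarray(q_init, dtype=float)
    for k in range(T):
        frame = np.full((len(chain.marker_labels), 3), np.nan)
        for i, o in enumerate(order):
            if o >= 0:
                frame[i] = markers.data[k, o]
        try:
            qk, rep = solve_frame(chain, frame, weights, q_prev)
        except ValueError:
            continue  # gap frame: left invalid
        Q[k] = qk
        valid[k] = True
        obj[k] = rep.objective
        rnorms[k] = [rep.residual_norms[lab] for lab in chain.marker_labels]
        iters[k] = rep.iterations
        conv[k] = rep.converged
        q_prev = qk
    report = SolveReport(obj, rnorms, iters, conv, list(chain.marker_labels))
    return QTrajectory(Q, markers.rate, valid), report


def tune_weights(
    chain: KinematicChain,
    markers: MarkerTrajectories,
    candidate_schemes: Sequence[WeightScheme],
) -> WeightScheme:
    """Pick the candidate minimizing mean weighted residual RMS.

    The score for a scheme is the frame-mean of
    sqrt(sum_i w_i ||r_i||^2 / sum_i w_i); ties (scores within 0.1 um)
    keep the first candidate.
    """
    if not candidate_schemes:
        raise ValueError("need at least one candidate weight scheme")
    best, best_score = candidate_schemes[0], np.inf
    for scheme in candidate_schemes:
        _q, rep = solve_trajectory(chain, markers, scheme)
        w = scheme.vector(chain)
        r2 = rep.residual_norms**2
        num = np.nansum(w[None, :] * r2, axis=1)
        den = np.sum(w[None, :] * np.isfinite(r2), axis=1)
        score = float(np.nanmean(np.sqrt(num / np.where(den > 0, den, np.nan))))
        if score < best_score - 1e-7:
            best, best_score = scheme, score
    return best


def export_poses(chain: KinematicChain, q_traj: QTrajectory) -> PoseStream:
    """Forward kinematics per frame -> 4x4 pose stream for all segments."""
    T = q_traj.n_frames
    data = np.full((T, len(chain.segments), 4, 4), np.nan)
    for k in range(T):
        if q_traj.valid[k] and np.all(np.isfinite(q_traj.q[k])):
            data[k] = _fk_array(chain, q_traj.q[k])
    return PoseStream(list(chain.segment_names), data, q_traj.rate)
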