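"""End-to-end synthetic study: simulate -> solve -> compare -> report.

One study emulates a capture session for one subject: ground-truth boxing
trials, a marker-based measurement chain (rendered markers + corruption +
subject scaling + multibody kinematic optimization at 300 Hz) and an
emulated markerless pose stream at 60 Hz with injected biases. The
agreement battery is computed at the lower rate after 8 Hz zero-phase
filtering, pooling differences across trials per variable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import agreement as ag
from . import kinematics as kv
from .containers import MarkerTrajectories, PoseStream, QTrajectory
from .kinematics import FilterSpec
from .mko import WeightScheme, export_poses, solve_trajectory
from .model import AnthroProfile, KinematicChain, build_chain, scale_template
from .synth import (
    CorruptionModel,
    PunchScript,
    SystemEmulation,
    corrupt_markers,
    emulate_markerless,
    generate_q_trajectory,
    render_markers,
)

STATIC_DURATION_S = 3.0


@dataclass
class StudyConfig:
    """Everything needed to reproduce one synthetic comparison study."""

    profile: AnthroProfile = field(default_factory=lambda: AnthroProfile("male", 1.90, 78.0))
    trials: list[PunchScript] = field(default_factory=lambda: [PunchScript()])
    corruption: CorruptionModel = field(default_factory=CorruptionModel)
    emulation: SystemEmulation = field(default_factory=SystemEmulation)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    weights: WeightScheme = field(default_factory=WeightScheme.default)
    front_side: str = "L"
    marker_rate: float = 300.0
    seed: int = 0
    edge_trim_s: float = 0.25  # trimmed from each end before pooling


@dataclass
class TrialResult:
    script: PunchScript
    q_true: QTrajectory
    q_est: QTrajectory
    ref_stream: PoseStream  # marker-based MKO export, 300 Hz
    test_stream: PoseStream  # emulated markerless export, 60 Hz
    true_peak_speed: dict[tuple[str, str], float]  # (segment base, side) -> m/s


@dataclass
class StudyResult:
    config: StudyConfig
    chain: KinematicChain  # generic template scaled to the profile
    scaled_chain: KinematicChain  # after static-capture subject scaling
    trials: list[TrialResult]
    report: ag.AgreementReport


def _side_label(seg_or_side: str, front_side: str) -> str:
    return "front" if seg_or_side == front_side else "rear"


def make_static_posture(chain: KinematicChain) -> np.ndarray:
    """Upright calibration posture, elbows slightly flexed off the bound."""
    q = chain.q_zero()
    for side in ("L", "R"):
        q[chain.q_index[(f"elbow_{side}", "flex_ext")]] = 0.3
    return q


def calibrate_subject_chain(
    chain: KinematicChain,
    corruption: CorruptionModel,
    rate: float = 300.0,
) -> tuple[KinematicChain, MarkerTrajectories]:
    """Render a corrupted static capture and scale the template from it."""
    n = int(STATIC_DURATION_S * rate)
    q_static = make_static_posture(chain)
    q_traj = QTrajectory(np.tile(q_static, (n, 1)), rate)
    static = corrupt_markers(render_markers(chain, q_traj), corruption, chain)
    return scale_template(chain, static), static


def run_trial(
    chain: KinematicChain,
    scaled_chain: KinematicChain,
    cfg: StudyConfig,
    script: PunchScript,
    trial_index: int,
) -> TrialResult:
    seed_t = cfg.seed * 97 + trial_index
    q_true = generate_q_trajectory(chain, script, cfg.marker_rate, seed_t, cfg.front_side)
    markers = render_markers(chain, q_true)
    corrupted = corrupt_markers(markers, cfg.corruption, chain, noise_seed=seed_t * 7 + 1)
    q_est, _rep = solve_trajectory(scaled_chain, corrupted, cfg.weights)
    ref_stream = export_poses(scaled_chain, q_est)
    test_stream = emulate_markerless(chain, q_true, cfg.emulation, seed=seed_t * 7 + 2)

    truth_stream = export_poses(chain, q_true)
    speeds = kv.com_speed(truth_stream, chain)
    peaks: dict[tuple[str, str], float] = {}
    for seg, v in speeds.items():
        if seg == "thorax":
            peaks[("thorax", "")] = float(np.nanmax(v))
        else:
            base, side = seg.rsplit("_", 1)
            peaks[(base, _side_label(side, cfg.front_side))] = float(np.nanmax(v))
    return TrialResult(script, q_true, q_est, ref_stream, test_stream, peaks)


def _trial_pairs(
    trial: TrialResult, cfg: StudyConfig, chain: KinematicChain, scaled_chain: KinematicChain
) -> tuple[dict, dict, dict]:
    """Filtered, rate-aligned, edge-trimmed paired series for one trial."""
    fs_lo = cfg.emulation.rate
    spec = cfg.filter_spec

    ref_ang = kv.joint_angle_series(trial.ref_stream, scaled_chain)
    test_ang = kv.joint_angle_series(trial.test_stream, chain)
    ref_spd = kv.com_speed(trial.ref_stream, scaled_chain)
    test_spd = kv.com_speed(trial.test_stream, chain)
    ref_ctr = kv.joint_center_series(trial.ref_stream, scaled_chain)
    test_ctr = kv.joint_center_series(trial.test_stream, chain)

    trim = int(round(cfg.edge_trim_s * fs_lo))

    def align(x300: np.ndarray) -> np.ndarray:
        return kv.resample_align(x300, cfg.marker_rate, fs_lo)

    def pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = min(len(a), len(b))
        sl = slice(trim, n - trim if trim else n)
        return a[sl], b[sl]

    angle_pairs: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (joint, side), test_arr in test_ang.items():
        ref_arr = ref_ang[(joint, side)]
        for k, axis in enumerate(kv.AXIS_LABELS):
            if (joint, axis) in kv.LOCKED_AXES:
                continue
            ref_f = kv.butterworth(align(ref_arr[:, k]), spec, fs_lo)
            test_f = kv.butterworth(test_arr[:, k], spec, fs_lo)
            r, t = pair(ref_f, test_f)
            angle_pairs[(joint, _side_label(side, cfg.front_side), axis)] = (
                np.rad2deg(r),
                np.rad2deg(t),
            )

    vel_pairs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for seg, test_v in test_spd.items():
        ref_f = kv.butterworth(align(ref_spd[seg]), spec, fs_lo)
        test_f = kv.butterworth(test_v, spec, fs_lo)
        r, t = pair(ref_f, test_f)
        if seg == "thorax":
            vel_pairs[("thorax", "")] = (r, t)
        else:
            base, side = seg.rsplit("_", 1)
            vel_pairs[(base, _side_label(side, cfg.front_side))] = (r, t)

    dist: dict[str, np.ndarray] = {}
    for name, test_c in test_ctr.items():
        base = name.split("_")[0]
        if base not in ("shoulder", "elbow", "wrist"):
            continue
        side = name.rsplit("_", 1)[1]
        ref_c = align(ref_ctr[name])
        n = min(len(ref_c), len(test_c))
        sl = slice(trim, n - trim if trim else n)
        d = np.linalg.norm(ref_c[sl] - test_c[sl], axis=1)
        dist[f"{base}_{_side_label(side, cfg.front_side)}"] = d
    return angle_pairs, vel_pairs, dist


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the complete synthetic comparison study described by ``cfg``."""
    chain = build_chain(cfg.profile)
    corruption = replace(cfg.corruption, seed=cfg.seed * 131 + 7)
    cfg = replace(cfg, corruption=corruption)
    scaled_chain, _static = calibrate_subject_chain(chain, corruption, cfg.marker_rate)

    trials = [
        run_trial(chain, scaled_chain, cfg, script, i) for i, script in enumerate(cfg.trials)
    ]

    pooled_angles: dict[tuple[str, str, str], list] = {}
    pooled_vels: dict[tuple[str, str], list] = {}
    pooled_dist: dict[str, list] = {}
    for trial in trials:
        ap, vp, dp = _trial_pairs(trial, cfg, chain, scaled_chain)
        for k, (r, t) in ap.items():
            pooled_angles.setdefault(k, [[], []])
            pooled_angles[k][0].append(r)
            pooled_angles[k][1].append(t)
        for k, (r, t) in vp.items():
            pooled_vels.setdefault(k, [[], []])
            pooled_vels[k][0].append(r)
            pooled_vels[k][1].append(t)
        for k, d in dp.items():
            pooled_dist.setdefault(k, []).append(d)

    angle_pairs = {
        k: ag.PairedSeries(np.concatenate(v[0]), np.concatenate(v[1]), units="deg")
        for k, v in pooled_angles.items()
    }
    vel_pairs = {
        k: ag.PairedSeries(np.concatenate(v[0]), np.concatenate(v[1]), units="m/s")
        for k, v in pooled_vels.items()
    }
    distances = {k: np.concatenate(v) for k, v in pooled_dist.items()}
    report = ag.build_report(angle_pairs, vel_pairs, distances)
    return StudyResult(cfg, chain, scaled_chain, trials, report)


# ---------------------------------------------------------------------------
# configuration parsing (YAML-friendly plain dicts)


def study_config_from_dict(doc: Mapping) -> StudyConfig:
    profile = AnthroProfile(**doc.get("profile", {"sex": "male", "height": 1.90, "mass": 78.0}))
    trials = [PunchScript(**t) for t in doc.get("trials", [{}])]
    corr = CorruptionModel(**doc.get("corruption", {}))
    emu_doc = dict(doc.get("emulation", {}))
    bias = {}
    for item in emu_doc.pop("angle_bias", []):
        bias[(item["joint"], item["dof"])] = np.deg2rad(item["deg"])
    offs = {}
    for item in emu_doc.pop("joint_center_offset", []):
        offs[item["joint"]] = tuple(item["offset_m"])
    emu = SystemEmulation(angle_bias=bias, joint_center_offset=offs, **emu_doc)
    filt = FilterSpec(**doc.get("filter", {}))
    weights = WeightScheme(segment_weights=dict(doc["weights"])) if "weights" in doc else WeightScheme.default()
    return StudyConfig(
        profile=profile,
        trials=trials,
        corruption=corr,
        emulation=emu,
        filter_spec=filt,
        weights=weights,
        front_side=doc.get("front_side", "L"),
        marker_rate=float(doc.get("marker_rate", 300.0)),
        seed=int(doc.get("seed", 0)),
        edge_trim_s=float(doc.get("edge_trim_s", 0.25)),
    )
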