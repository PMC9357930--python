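"""Text file formats: TRC marker files, pose/coordinate CSV, chain YAML.

All writers use fixed numeric formatting so identical inputs produce
byte-identical files.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import AgreementReport
from .containers import MarkerTrajectories, PoseStream, QTrajectory
from .model import AnthroProfile, JointConstraint, KinematicChain, SegmentSpec

_FMT = "%.8f"


# ---------------------------------------------------------------------------
# TRC (tab-delimited marker trajectories)


def write_trc(markers: MarkerTrajectories, path: str | Path) -> None:
    path = Path(path)
    T, M, _ = markers.data.shape
    with path.open("w", newline="\n") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(
            f"{markers.rate:g}\t{markers.rate:g}\t{T}\t{M}\tm\t{markers.rate:g}\t1\t{T}\n"
        )
        fh.write("Frame#\tTime\t" + "\t\t\t".join(markers.labels) + "\t\t\n")
        axes = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(M))
        fh.write("\t\t" + axes + "\n\n")
        for k in range(T):
            vals = "\t".join(
                "" if not np.isfinite(v) else _FMT % v for v in markers.data[k].ravel()
            )
            fh.write(f"{k + 1}\t{_FMT % (k / markers.rate)}\t{vals}\n")


def read_trc(path: str | Path) -> MarkerTrajectories:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 5:
        raise ValueError(f"{path}: truncated TRC header")
    meta = lines[2].split("\t")
    rate = float(meta[0])
    n_markers = int(meta[3])
    units = meta[4].strip().lower()
    scale = 0.001 if units == "mm" else 1.0
    labels = [s for s in lines[3].split("\t")[2:] if s.strip()]
    if len(labels) != n_markers:
        raise ValueError(f"{path}: header lists {n_markers} markers, found {len(labels)} labels")
    if n_markers == 0:
        raise ValueError(f"{path}: no markers in file")
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        vals = [float(p) if p.strip() else np.nan for p in parts[2 : 2 + 3 * n_markers]]
        vals += [np.nan] * (3 * n_markers - len(vals))
        rows.append(vals)
    data = np.asarray(rows, dtype=float).reshape(len(rows), n_markers, 3) * scale
    return MarkerTrajectories(labels, data, rate)


# ---------------------------------------------------------------------------
# pose stream CSV

_POSE_COLS = ["frame", "time_s", "segment"] + [
    f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)
] + ["tx", "ty", "tz"]


def write_poses(stream: PoseStream, path: str | Path) -> None:
    rows = []
    for k in range(stream.n_frames):
        for s, seg in enumerate(stream.segments):
            T = stream.data[k, s]
            rows.append(
                [k, k / stream.rate, seg, *T[:3, :3].ravel().tolist(), *T[:3, 3].tolist()]
            )
    df = pd.DataFrame(rows, columns=_POSE_COLS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_poses(path: str | Path, rate: float | None = None) -> PoseStream:
    df = pd.read_csv(path)
    missing = set(_POSE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing pose columns {sorted(missing)}")
    segments = list(dict.fromkeys(df["segment"]))
    frames = sorted(df["frame"].unique())
    if rate is None:
        times = df.drop_duplicates("frame")["time_s"].to_numpy()
        if len(times) < 2:
            raise ValueError(f"{path}: cannot infer rate from a single frame; pass rate=")
        rate = float(1.0 / np.mean(np.diff(times)))
    data = np.full((len(frames), len(segments), 4, 4), np.nan)
    fidx = {f: i for i, f in enumerate(frames)}
    sidx = {s: i for i, s in enumerate(segments)}
    rcols = [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
    for _, row in df.iterrows():
        T = np.eye(4)
        R = np.array([row[c] for c in rcols], dtype=float).reshape(3, 3)
        T[:3, :3] = R
        T[:3, 3] = [row["tx"], row["ty"], row["tz"]]
        if np.all(np.isfinite(R)):
            if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
                raise ValueError(
                    f"{path}: non-orthonormal rotation at frame {int(row['frame'])}, "
                    f"segment {row['segment']}"
                )
        else:
            T[:] = np.nan
        data[fidx[row["frame"]], sidx[row["segment"]]] = T
    return PoseStream(segments, data, rate)


# ---------------------------------------------------------------------------
# generalized-coordinate CSV


def write_q(q_traj: QTrajectory, path: str | Path) -> None:
    cols = {"frame": np.arange(q_traj.n_frames), "time_s": q_traj.time, "valid": q_traj.valid.astype(int)}
    for j in range(q_traj.n_q):
        cols[f"q{j}"] = q_traj.q[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_q(path: str | Path, rate: float | None = None) -> QTrajectory:
    df = pd.read_csv(path)
    qcols = [c for c in df.columns if c.startswith("q") and c[1:].isdigit()]
    qcols.sort(key=lambda c: int(c[1:]))
    if rate is None:
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer rate; pass rate=")
        rate = float(1.0 / np.mean(np.diff(t)))
    return QTrajectory(df[qcols].to_numpy(), rate, df["valid"].to_numpy().astype(bool))


# ---------------------------------------------------------------------------
# chain YAML


def chain_to_yaml(chain: KinematicChain, path: str | Path) -> None:
    doc = {
        "profile": None
        if chain.profile is None
        else {"sex": chain.profile.sex, "height": chain.profile.height, "mass": chain.profile.mass},
        "segments": [
            {
                "name": s.name,
                "length": float(s.length),
                "com_offset": [float(v) for v in s.com_offset],
                "frame_definition": s.frame_definition,
            }
            for s in chain.segments
        ],
        "joints": [
            {
                "name": j.name,
                "parent": j.parent,
                "child": j.child,
                "free_rotations": list(j.free_rotations),
                "free_translations": list(j.free_translations),
                "offset_in_parent": [float(v) for v in j.offset_in_parent],
            }
            for j in chain.joints
        ],
        "markers": {
            m: {"segment": seg, "local": [float(v) for v in pos]}
            for m, (seg, pos) in chain.marker_local_positions.items()
        },
        "extra_joint_centers": {
            n: {"segment": seg, "local": [float(v) for v in pos]}
            for n, (seg, pos) in chain.extra_joint_centers.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def chain_from_yaml(path: str | Path) -> KinematicChain:
    doc = yaml.safe_load(Path(path).read_text())
    profile = None
    if doc.get("profile"):
        profile = AnthroProfile(**doc["profile"])
    segments = [
        SegmentSpec(d["name"], d["length"], np.array(d["com_offset"]), d["frame_definition"])
        for d in doc["segments"]
    ]
    joints = [
        JointConstraint(
            d["name"],
            d["parent"],
            d["child"],
            tuple(d["free_rotations"]),
            tuple(d["free_translations"]),
            np.array(d["offset_in_parent"]),
        )
        for d in doc["joints"]
    ]
    markers = {m: (d["segment"], np.array(d["local"])) for m, d in doc["markers"].items()}
    extra = {
        n: (d["segment"], np.array(d["local"]))
        for n, d in doc.get("extra_joint_centers", {}).items()
    }
    return KinematicChain(segments, joints, markers, extra, profile)


# ---------------------------------------------------------------------------
# agreement report output


def write_report(report: AgreementReport, outdir: str | Path, stamp: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.angles.to_csv(outdir / "angles.csv", index=False, float_format="%.6g")
    report.velocities.to_csv(outdir / "velocities.csv", index=False, float_format="%.6g")
    report.joint_centers.to_csv(outdir / "joint_centers.csv", index=False, float_format="%.6g")
    (outdir / "report.txt").write_text(report.to_text() + "\n")
    payload = {
        "angles": report.angles.to_dict(orient="records"),
        "velocities": report.velocities.to_dict(orient="records"),
        "joint_centers": report.joint_centers.to_dict(orient="records"),
    }
    if stamp:
        payload["meta"] = stamp
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
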