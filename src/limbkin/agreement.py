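"""Method-agreement statistics: Bland-Altman, R^2, RMSD, distance summaries.

The battery compares a test method (markerless video stream) against a
reference (marker-based MKO) on pooled paired series. The Bland-Altman
branch follows the distribution of the paired differences: for normal
differences bias = mean and CI = 1.96 * SD; otherwise bias = median and
CI = 1.45 * IQR. Quantiles use the linear-interpolation definition.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

SHAPIRO_ALPHA = 0.05
SHAPIRO_MAX_N = 5000

#: joint axes never reported (locked in the multibody optimization)
LOCKED_ROWS = {("elbow", "abd_add"), ("wrist", "int_ext")}

AXIS_TITLES = {
    "abd_add": "Abduction/Adduction",
    "int_ext": "Internal/External",
    "flex_ext": "Flexion/Extension",
}


@dataclass
class PairedSeries:
    """Pooled paired measurements of one variable from the two methods."""

    reference: np.ndarray
    test: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float).ravel()
        tst = np.asarray(self.test, dtype=float).ravel()
        if ref.shape != tst.shape:
            raise ValueError("reference and test must have equal length")
        keep = np.isfinite(ref) & np.isfinite(tst)
        self.reference, self.test = ref[keep], tst[keep]
        if len(self.reference) < 3:
            raise ValueError("need at least 3 finite pairs")

    @property
    def differences(self) -> np.ndarray:
        return self.test - self.reference

    @property
    def n(self) -> int:
        return len(self.reference)


@dataclass
class AgreementResult:
    b: float  # bias: mean (normal branch) or median of differences
    ci: float  # 1.96*SD or 1.45*IQR half-interval
    r2: float  # squared Pearson correlation (NaN when undefined)
    rmsd: float
    n: int
    normal: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.ci < 0 or (np.isfinite(self.rmsd) and self.rmsd < 0):
            raise ValueError("CI and RMSD must be non-negative")


def normality_check(x: np.ndarray, alpha: float = SHAPIRO_ALPHA) -> bool:
    """Shapiro-Wilk non-rejection at level alpha.

    Samples larger than 5000 are thinned to evenly spaced indices so the
    outcome is deterministic. Degenerate (constant) input returns False.
    Requires n >= 8.
    """
    x = np.asarray(x, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) < 8:
        raise ValueError(f"normality check needs n >= 8, got {len(x)}")
    if np.ptp(x) == 0:
        return False
    if len(x) > SHAPIRO_MAX_N:
        idx = np.linspace(0, len(x) - 1, SHAPIRO_MAX_N).round().astype(int)
        x = x[idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bool(stats.shapiro(x).pvalue >= alpha)


def iqr(x: np.ndarray) -> float:
    q1, q3 = np.quantile(np.asarray(x, dtype=float), [0.25, 0.75])
    return float(q3 - q1)


def bland_altman(p: PairedSeries) -> AgreementResult:
    """Bland-Altman bias and CI with normality branching, plus R^2 and RMSD."""
    d = p.differences
    if np.ptp(d) == 0:
        # all pairs agree identically (up to a shared constant)
        b = float(d[0])
        return AgreementResult(
            b=b, ci=0.0, r2=r_squared(p), rmsd=abs(b), n=p.n, normal=False, degenerate=True
        )
    normal = normality_check(d) if p.n >= 8 else True
    if normal:
        b = float(np.mean(d))
        ci = float(1.96 * np.std(d, ddof=1))
    else:
        b = float(np.median(d))
        ci = float(1.45 * iqr(d))
    return AgreementResult(b=b, ci=ci, r2=r_squared(p), rmsd=rmsd(p), n=p.n, normal=normal)


def rmsd(p: PairedSeries) -> float:
    """Root mean square difference sqrt(mean((test - reference)^2))."""
    return float(np.sqrt(np.mean(p.differences**2)))


def r_squared(p: PairedSeries) -> float:
    """Squared Pearson correlation between the two methods' series.

    A pure association measure: insensitive to offset and scale (a constant
    offset still yields R^2 = 1). NaN when the reference has no variance.
    """
    if np.ptp(p.reference) == 0 or np.ptp(p.test) == 0:
        warnings.warn("zero-variance series; R^2 undefined")
        return float("nan")
    r = np.corrcoef(p.reference, p.test)[0, 1]
    return float(r**2)


def summarize_distances(
    distances: Mapping[str, np.ndarray], to_cm: bool = True
) -> pd.DataFrame:
    """Pooled median (IQR) of joint-center distances per joint, in cm."""
    rows = []
    scale = 100.0 if to_cm else 1.0
    for joint, d in distances.items():
        d = np.asarray(d, dtype=float).ravel()
        d = d[np.isfinite(d)]
        if len(d) < 3:
            warnings.warn(f"joint {joint!r} has fewer than 3 samples; omitted")
            continue
        rows.append(
            {
                "joint": joint,
                "median": float(np.median(d)) * scale,
                "iqr": iqr(d) * scale,
                "n": len(d),
            }
        )
    return pd.DataFrame(rows, columns=["joint", "median", "iqr", "n"])


@dataclass
class AgreementReport:
    """The full statistical battery in table form.

    ``angles``: per joint/side/axis Bland-Altman rows (degrees);
    ``velocities``: per segment/side rows (m/s);
    ``joint_centers``: median (IQR) distance summary (cm).
    """

    angles: pd.DataFrame
    velocities: pd.DataFrame
    joint_centers: pd.DataFrame

    def to_text(self) -> str:
        lines = [
            "Joint angles (deg): Bland-Altman b, CI, R^2, RMSD",
            self.angles.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
            "",
            "Segment velocity magnitudes (m/s): Bland-Altman b, CI, R^2, RMSD",
            self.velocities.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "Joint-center distances, median (IQR), cm",
            self.joint_centers.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
        ]
        return "\n".join(lines)


_STAT_COLS = ["b", "ci", "r2", "rmsd", "n", "normal"]


def _result_row(res: AgreementResult) -> dict:
    return {
        "b": res.b, "ci": res.ci, "r2": res.r2, "rmsd": res.rmsd,
        "n": res.n, "normal": res.normal,
    }


def build_report(
    angle_pairs: Mapping[tuple[str, str, str], PairedSeries],
    velocity_pairs: Mapping[tuple[str, str], PairedSeries],
    distances: Mapping[str, np.ndarray] | None = None,
) -> AgreementReport:
    """Assemble the agreement tables.

    ``angle_pairs`` keys are (joint, side, axis) with angles in degrees;
    ``velocity_pairs`` keys are (segment, side) in m/s; ``distances`` maps
    joint names to pooled distance samples in meters. Values may be
    PairedSeries or raw (reference, test) tuples. Locked joint axes are
    dropped; variables that fail to evaluate are omitted with a warning.
    """

    def _coerce(pair):
        if isinstance(pair, PairedSeries):
            return pair
        return PairedSeries(*pair)

    angle_rows = []
    for (joint, side, axis), pair in angle_pairs.items():
        if (joint, axis) in LOCKED_ROWS:
            continue
        try:
            res = bland_altman(_coerce(pair))
        except ValueError as err:
            warnings.warn(f"angle {joint}/{side}/{axis} omitted: {err}")
            continue
        angle_rows.append({"joint": joint, "side": side, "axis": axis, **_result_row(res)})
    vel_rows = []
    for (segment, side), pair in velocity_pairs.items():
        try:
            res = bland_altman(_coerce(pair))
        except ValueError as err:
            warnings.warn(f"velocity {segment}/{side} omitted: {err}")
            continue
        vel_rows.append({"segment": segment, "side": side, **_result_row(res)})
    angles = pd.DataFrame(angle_rows, columns=["joint", "side", "axis"] + _STAT_COLS)
    velocities = pd.DataFrame(vel_rows, columns=["segment", "side"] + _STAT_COLS)
    dist = summarize_distances(distances) if distances else pd.DataFrame(
        columns=["joint", "median", "iqr", "n"]
    )
    return AgreementReport(angles, velocities, dist)
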