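# limbkin

Upper-limb multibody kinematics and method-agreement analysis for highly
dynamic arm movements (shadow boxing), built for one question: **if a
markerless video system and a marker-based optoelectronic system watch the
same punches, how do their joint centers, joint angles and segment
velocities disagree — and can an analysis pipeline quantify that agreement
correctly?** Real elite-athlete capture data of this kind is not publicly
available, so the package ships a synthetic-motion generator with known
ground truth and validates the *entire* chain against it.

Who it is for: biomechanists and sports scientists who want a tested,
self-contained reference implementation of marker-based multibody kinematic
optimization plus the standard agreement battery, and a controllable
sandbox for studying how marker artifact, model scaling and inter-system
biases propagate into the reported statistics.

## What is inside

* **Multibody model** — thorax root (6 DoF) with clavicle (2 rotational
  DoF), upper arm (3), forearm (2, abduction/adduction locked) and hand
  (2, axial rotation locked) per side; 24 generalized coordinates `q` in
  minimal coordinates, so constraints hold exactly. Elbow/wrist centers
  are epicondyle/styloid midpoints; shoulder and spine centers are
  regression-style fixed points.
* **MKO** (multibody kinematic optimization): per frame, the weighted
  nonlinear least squares

  ```
  min_q  Σᵢ wᵢ ‖mᵢ − mᵢ(q)‖²
  ```

  over the chain's free coordinates (trust-region solver, analytic
  geometric Jacobian, warm starts, segment-specific weights ordered
  thorax > upper arm > forearm > hand).
* **Kinematic variables** — intrinsic Z–X–Y cardan joint angles
  (flex/ext, abd/add, int/ext), 3D joint-center distances between two
  streams, segment-CoM speed magnitudes, zero-phase 4th-order Butterworth
  filtering at 8 Hz, and anti-aliased 300 Hz → 60 Hz alignment.
* **Agreement battery** — Bland–Altman bias `b` with normality branching
  (`b = mean(d), CI = 1.96·SD` for normal differences, else
  `b = median(d), CI = 1.45·IQR`), squared Pearson `R²`, RMSD, and
  median (IQR) joint-center distances in cm.
* **Synthetic study** — scripted shadow-boxing trials (straights, double,
  jab+hook, uppercut+hook+hook) with minimum-jerk punches calibrated to a
  target hand peak speed (default 7.5 m/s), footwork sway, soft-tissue-
  artifact-like marker corruption, subject scaling from a static capture,
  and an emulated 60 Hz markerless pose stream with injectable per-axis
  biases.

## Worked example

Simulate one subject throwing three straight lefts at 7.5 m/s, corrupt the
markers with soft-tissue artifact and jitter, emulate a 60 Hz markerless
stream carrying a +2.4° shoulder-flexion bias, solve, and compare:

```python
import numpy as np
import limbkin as lk
from limbkin.pipeline import StudyConfig, run_study
from limbkin.synth import SystemEmulation, CorruptionModel

cfg = StudyConfig(
    trials=[lk.PunchScript(punch_type="direct_face", side="front",
                           repetitions=3, peak_hand_speed=7.5)],
    corruption=CorruptionModel(placement_offset_sd=0.0),
    emulation=SystemEmulation(angle_bias={("shoulder_L", "flex_ext"): np.deg2rad(2.4)}),
    seed=7,
)
result = run_study(cfg)
print(result.report.to_text())
```

prints (abridged):

```
Joint angles (deg): Bland-Altman b, CI, R^2, RMSD
   joint  side     axis     b    ci   r2  rmsd   n  normal
shoulder front flex_ext  2.40  1.50 1.00  2.52 263    True
shoulder front  abd_add -0.18  2.14 0.97  1.10 263    True
shoulder  rear flex_ext  0.31  1.89 0.00  0.90 263   False
   elbow front flex_ext -0.26  1.82 1.00  1.21 263   False
   elbow front  int_ext -0.76 10.11 0.45  5.20 263    True
   wrist front flex_ext  0.79  6.58 0.73  3.38 263   False
...
Segment velocity magnitudes (m/s): Bland-Altman b, CI, R^2, RMSD
  segment  side      b    ci    r2  rmsd   n  normal
   thorax       -0.008 0.036 0.999 0.020 263    True
     hand front -0.017 0.093 0.999 0.062 263   False
...
Joint-center distances, median (IQR), cm
         joint  median  iqr   n
shoulder_front    0.36 0.20 263
   elbow_front    1.41 0.33 263
```

Reading it: the injected +2.4° flexion bias is recovered exactly in the
front-shoulder `b`; the unbiased rear side sits near zero. Elbow axial
rotation shows the widest interval (CI ≈ 10°) — with the front arm near
full extension, long-axis rotation is poorly observable, so marker artifact
inflates it far more than flexion. Velocities agree to centi-m/s; `R²`
is NaN where a guard arm's series has no variance, and degrades to ~0 for
angles that barely move (an association measure needs signal). Locked DoFs
(elbow abd/add, wrist int/ext) have no rows at all.

The test suite's end-to-end checks run the same pipeline with a 5°
shoulder bias, a 3 cm elbow-center offset and a 7.5 m/s peak-speed target,
and require recovery within ±0.5°, ±0.15 cm and 2 % respectively.

## Command line

```bash
limbkin simulate --seed 1 --out study/          # markers (TRC), truth, markerless poses (CSV)
limbkin solve --markers study/trial00_markers.trc --chain study/chain.yaml \
              --static study/static.trc --out poses.csv
limbkin compare --poses-ref poses.csv --poses-test study/trial00_markerless_poses.csv \
                --chain study/chain.yaml --out vars.csv
limbkin report --variables vars.csv --out tables/
limbkin run-all --seed 1 --out tables/          # the whole study in one go
```

Every stage is re-entrant from files; identical config and seed give
byte-identical outputs. Marker interchange uses the text TRC format and a
pose CSV dialect (`frame, time_s, segment, r11..r33, tx, ty, tz`).

## Layout

```
src/limbkin/
  model.py       chain, forward kinematics, joint centers, subject scaling
  mko.py         weighted multibody kinematic optimization
  kinematics.py  cardan angles, CoM speeds, filtering, rate alignment
  agreement.py   Bland-Altman / R² / RMSD battery and report tables
  synth.py       boxing-motion generator, corruption, markerless emulation
  pipeline.py    the end-to-end synthetic study
  io.py, cli.py  TRC/CSV/YAML formats and the command line
docs/methods.md  model, conventions, design choices, known limitations
```
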