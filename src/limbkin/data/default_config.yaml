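# Default synthetic study: one subject, five shadow-boxing trials
# (marker stream 300 Hz, emulated video stream 60 Hz).
profile: {sex: male, height: 1.90, mass: 78.0}
front_side: L
marker_rate: 300
seed: 1
edge_trim_s: 0.25
trials:
  - {punch_type: direct_face, side: front, repetitions: 4, peak_hand_speed: 7.5, duration_per_punch: 0.6}
  - {punch_type: direct_body, side: front, repetitions: 4, peak_hand_speed: 6.5, duration_per_punch: 0.6}
  - {punch_type: double_direct, side: front, repetitions: 4, peak_hand_speed: 7.5, duration_per_punch: 0.6}
  - {punch_type: jab_hook, side: rear, repetitions: 4, peak_hand_speed: 6.0, duration_per_punch: 0.6}
  - {punch_type: uppercut_hook_hook, side: front, repetitions: 4, peak_hand_speed: 5.0, duration_per_punch: 0.6}
corruption:
  placement_offset_sd: 0.005
  sta_bandwidth: 3.0
  jitter_sd: 0.0005
emulation:
  rate: 60
  pose_noise_rot_sd: 0.008   # rad, ~0.5 deg
  pose_noise_trans_sd: 0.004 # m
  angle_bias:
    - {joint: shoulder_L, dof: flex_ext, deg: 2.4}
filter: {order: 4, cutoff: 8.0}
weights: {thorax: 10, clavicle: 5, upper_arm: 5, forearm: 2, hand: 1}
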