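# Sex-specific anthropometric template constants.
#
# length_frac: segment long-axis length as a fraction of stature (m/m).
# com_frac:    centre-of-mass position along the proximal->distal long axis,
#              as a fraction of segment length.
#
# Values are editable template constants in the style of the published
# scaling/CoM regressions (Dumas & Wojtusch; Drillis & Contini order of
# magnitude). The pipeline's correctness does not depend on the exact numbers
# because the synthetic generator and the solver share one chain.
male:
  length_frac:
    thorax: 0.200
    clavicle: 0.100
    upper_arm: 0.186
    forearm: 0.146
    hand: 0.108
  com_frac:
    thorax: 0.50
    clavicle: 0.50
    upper_arm: 0.443
    forearm: 0.417
    hand: 0.361
female:
  length_frac:
    thorax: 0.192
    clavicle: 0.098
    upper_arm: 0.183
    forearm: 0.141
    hand: 0.103
  com_frac:
    thorax: 0.50
    clavicle: 0.50
    upper_arm: 0.464
    forearm: 0.424
    hand: 0.383
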