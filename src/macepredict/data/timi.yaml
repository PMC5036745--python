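# TIMI risk score for UA/NSTEMI, transcribed from the original publication
# (Antman EM et al., JAMA 2000;284:835-42).  Seven predictors, one point
# each.
name: TIMI
variables:
  - name: age_ge_65
    kind: binary
    points: 1
  - name: risk_factors_ge_3
    kind: binary
    points: 1
  - name: known_cad
    kind: binary
    points: 1
  - name: aspirin_recent
    kind: binary
    points: 1
  - name: severe_angina
    kind: binary
    points: 1
  - name: st_deviation
    kind: binary
    points: 1
  - name: elevated_markers
    kind: binary
    points: 1
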