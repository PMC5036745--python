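# GRACE in-hospital mortality additive point table, transcribed from the
# original GRACE registry risk-model publication (Granger CB et al.,
# Arch Intern Med 2003;163:2345-53).  Numeric bins are "value <= upper";
# a null upper bound is the open top bin.  Creatinine is in mg/dL.
name: GRACE
variables:
  - name: age
    kind: numeric
    direction: increasing
    bins:
      - {upper: 29, points: 0}
      - {upper: 39, points: 8}
      - {upper: 49, points: 25}
      - {upper: 59, points: 41}
      - {upper: 69, points: 58}
      - {upper: 79, points: 75}
      - {upper: 89, points: 91}
      - {upper: null, points: 100}
  - name: heart_rate
    kind: numeric
    direction: increasing
    bins:
      - {upper: 49.9, points: 0}
      - {upper: 69.9, points: 3}
      - {upper: 89.9, points: 9}
      - {upper: 109.9, points: 15}
      - {upper: 149.9, points: 24}
      - {upper: 199.9, points: 38}
      - {upper: null, points: 46}
  - name: sbp
    kind: numeric
    direction: decreasing
    bins:
      - {upper: 79.9, points: 58}
      - {upper: 99.9, points: 53}
      - {upper: 119.9, points: 43}
      - {upper: 139.9, points: 34}
      - {upper: 159.9, points: 24}
      - {upper: 199.9, points: 10}
      - {upper: null, points: 0}
  - name: creatinine
    kind: numeric
    direction: increasing
    bins:
      - {upper: 0.39, points: 1}
      - {upper: 0.79, points: 4}
      - {upper: 1.19, points: 7}
      - {upper: 1.59, points: 10}
      - {upper: 1.99, points: 13}
      - {upper: 3.99, points: 21}
      - {upper: null, points: 28}
  - name: killip_class
    kind: numeric
    direction: increasing
    bins:
      - {upper: 1, points: 0}
      - {upper: 2, points: 20}
      - {upper: 3, points: 39}
      - {upper: null, points: 59}
  - name: cardiac_arrest
    kind: binary
    points: 39
  - name: st_deviation
    kind: binary
    points: 28
  - name: elevated_enzymes
    kind: binary
    points: 14
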