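# The four representative published extraction rules over annotated clause
# text, in the (?<NAME>...) named-group dialect in which they were printed.
# The [Body Part] + [Description] pattern is printed with unbalanced
# parentheses and a stray "\*"; it is restored here to a compilable form that
# admits the enumeration mark between consecutive body-part symbols, which is
# what its worked example requires.
- name: body_part_symptom
  pattern: "(?<BPPatternSet>(BP#[0-9]+#)+)[\\u4e00-\\u9fa5]*(?<STDGPatternSet>(ST#[0-9]+#)+)"
  emit: [BPPatternSet, STDGPatternSet]
  priority: 1
- name: body_part_description
  pattern: "(?<BPPatternSet>(BP#[0-9]+#[、\\\\]?)+)[\\u4e00-\\u9fa5]*(?<DSPattern>DS#[0-9]+#)"
  emit: [BPPatternSet, DSPattern]
  priority: 2
- name: diagnosis
  pattern: "(?<DGPattern>(DG#[0-9]+#))"
  emit: [DGPattern]
  priority: 3
- name: medication
  pattern: "(?<MDPatternSet>MD#[0-9]+#)"
  emit: [MDPatternSet]
  priority: 4
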