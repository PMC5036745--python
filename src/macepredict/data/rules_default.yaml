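# Default rule set: the four published rules plus combinatorial variants
# covering the remaining semantic classes.  Lower priority runs first;
# symbols consumed by an earlier match are skipped by later rules, so the
# single-symbol rules act as fallbacks for symbols no compound rule claimed.
- name: body_part_symptom
  pattern: "(?<BPPatternSet>(BP#[0-9]+#)+)[\\u4e00-\\u9fa5]*(?<STDGPatternSet>((ST|DG)#[0-9]+#)+)"
  emit: [BPPatternSet, STDGPatternSet]
  priority: 1
  class: ST
- name: body_part_description
  pattern: "(?<BPPatternSet>(BP#[0-9]+#[、\\\\]?)+)[\\u4e00-\\u9fa5]*(?<DSPattern>DS#[0-9]+#)"
  emit: [BPPatternSet, DSPattern]
  priority: 2
  class: DS
- name: examination_description
  pattern: "(?<EXPattern>EX#[0-9]+#)[\\u4e00-\\u9fa5]*(?<DSPattern>DS#[0-9]+#)"
  emit: [EXPattern, DSPattern]
  priority: 3
  class: DS
- name: diagnosis
  pattern: "(?<DGPattern>DG#[0-9]+#)"
  emit: [DGPattern]
  priority: 4
  class: DG
- name: medication
  pattern: "(?<MDPatternSet>MD#[0-9]+#)"
  emit: [MDPatternSet]
  priority: 5
  class: MD
- name: symptom
  pattern: "(?<STPattern>ST#[0-9]+#)"
  emit: [STPattern]
  priority: 6
  class: ST
- name: personal_history
  pattern: "(?<PSPattern>PS#[0-9]+#)"
  emit: [PSPattern]
  priority: 7
  class: PS
- name: surgery
  pattern: "(?<SGPattern>SG#[0-9]+#)"
  emit: [SGPattern]
  priority: 8
  class: SG
- name: ecg_finding
  pattern: "(?<ECPattern>EC#[0-9]+#)"
  emit: [ECPattern]
  priority: 9
  class: EC
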