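# eppgi-default: reconstructed pregnancy/gestation extraction rule set.
#
# Keyword patterns are anchored on the published category examples
# (birth-event keywords, gravidity/parity shorthand, termination surgery,
# labor/miscarriage-induction medications, fetus descriptions, HCG
# positivity thresholds, denial-style negations).  Include rules are
# corpus-wide (empty scope): sensitive reproductive information is
# deliberately searched in every sub-dataset, not only the diagnosis sheet.
# Users with an authoritative in-house list can swap this file wholesale.
name: eppgi-default
version: "1.0"
rules:
  - rule_id: birth_events
    category: gestation_history
    pattern: "助产|难产|平产|顺产|早产|死产|死胎"
  - rule_id: gravidity_parity
    category: gestation_history
    pattern: "G\\d+P\\d+|孕\\d+产\\d+"
  - rule_id: gestation_phrases
    category: gestation_history
    pattern: "流产史|生育史|剖宫产史|足月产|分娩"
  - rule_id: pregnancy_diagnosis
    category: diagnosis
    pattern: "妊娠|宫内孕|宫外孕|先兆流产|早孕|葡萄胎|产褥"
  - rule_id: hcg_positive_text
    category: diagnosis
    pattern: "HCG阳性|尿妊娠试验阳性|血HCG升高"
  - rule_id: termination_surgery
    category: surgery
    pattern: "人工流产术|药物流产|清宫术|引产术|剖宫产术|会阴侧切|取胚术"
  - rule_id: pregnancy_complaint
    category: chief_complaint
    pattern: "停经\\d+[天周月]|待产|见红|胎动减少"
  - rule_id: induction_medication
    category: medication
    pattern: "米非司酮|米索前列醇|缩宫素|催产素|利凡诺|地诺前列酮"
  - rule_id: fetus_description
    category: fetus_description
    pattern: "胎心|胎动|胎位|胎儿|双胎|单活胎|胎盘"
  - rule_id: hcg_over_10_ngL
    category: lab_threshold
    analyte: HCG
    threshold: 10
    threshold_unit: ng/L
  - rule_id: hcg_over_25_IUL
    category: lab_threshold
    analyte: HCG
    threshold: 25
    threshold_unit: IU/L
  - rule_id: denial_history
    category: exclusion
    polarity: exclude
    pattern: "否认[^。；;，,]{0,20}史"
  - rule_id: negative_findings
    category: exclusion
    polarity: exclude
    pattern: "无[^。；;，,]{0,8}(早产|流产|死胎|死产|难产|分娩|妊娠)史|未见(胎心|胎动|胎儿)|非孕"
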