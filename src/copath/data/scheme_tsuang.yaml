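name: tsuang
lb_rule: {none: LB-, brainstem: excluded, limbic: LB+, neocortical: LB+, olfactory_or_unspecified: excluded}
ad_rule:
  LB+:
    '0': [AD-, AD-, AD-, AD-]
    '1': [AD-, AD-, AD-, AD-]
    '2': [AD-, AD-, AD-, AD-]
    '3': [AD-, AD-, AD-, AD-]
    '4': [AD-, AD-, AD+, AD+]
    '5': [AD-, AD-, AD+, AD+]
    '6': [AD-, AD-, AD+, AD+]
  LB-:
    '0': [AD-, AD-, AD-, AD-]
    '1': [AD-, AD-, AD-, AD-]
    '2': [AD-, AD-, AD-, AD-]
    '3': [AD-, AD-, AD-, AD-]
    '4': [AD-, AD-, AD+, AD+]
    '5': [AD-, AD-, AD+, AD+]
    '6': [AD-, AD-, AD+, AD+]
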