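# Reduction chains for the distal ECA vascular tree.  Same conventions
# as recipes_ica.yaml: one entry per intermediate; R* and C* names of an
# index share the evaluated element.
subtree: eca-distal
entries:
  - name: R20
    aliases: [C20]
    mode: parallel
    children: [{ref: B36}, {ref: B35}]
    printed_resistance: 3.76e7
    printed_compliance: 2.08e-12
    note: B36 and B35 in parallel
  - name: R21
    aliases: [C21]
    mode: series
    children: [{ref: R20}, {ref: B38}]
    printed_resistance: 7.28e7
    printed_compliance: 1.67e-13
    note: R20 and B38 in series
  - name: R22
    aliases: [C22]
    mode: parallel
    children: [{ref: R21}, {ref: B34}]
    printed_resistance: 7.23e7
    printed_compliance: 1.86e-13
    note: R21 and B34 in parallel
  - name: R23
    aliases: [C23]
    mode: series
    children: [{ref: R22}, {ref: B38}]
    printed_resistance: 1.08e8
    printed_compliance: 9.19e-14
    note: R22 and B38 in series
  - name: R24
    aliases: [C24]
    mode: parallel
    children: [{ref: R23}, {ref: B33}]
    printed_resistance: 9.57e7
    printed_compliance: 2.75e-13
    note: R23 and B33 in parallel
  - name: R25
    aliases: [C25]
    mode: series
    children: [{ref: R24}, {ref: B37}]
    printed_resistance: 1.07e8
    printed_compliance: 1.68e-13
    note: R24 and B37 in series
  - name: R26
    aliases: [C26]
    mode: parallel
    children: [{ref: B31}, {ref: B32}]
    printed_resistance: 3.30e7
    printed_compliance: 6.64e-13
    note: B31 and B32 in parallel
  - name: R27
    aliases: [C27]
    mode: parallel
    children: [{ref: R25}, {ref: R26}]
    printed_resistance: 2.52e7
    printed_compliance: 8.32e-13
    note: R25 and R26 in parallel
  - name: R28
    aliases: [C28]
    mode: series
    children: [{ref: R27}, {ref: B37}]
    printed_resistance: 3.64e7
    printed_compliance: 2.84e-13
    note: R27 and B37 in series
  - name: R29
    aliases: [C29]
    mode: parallel
    children: [{ref: R28}, {ref: B29}, {ref: B30}]
    printed_resistance: 3.19e7
    printed_compliance: 3.89e-13
    note: R28, B29 and B30 in parallel for the distal lump of the ECA
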