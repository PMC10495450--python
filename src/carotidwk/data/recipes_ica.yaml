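# Reduction chains for the distal ICA vascular tree (MCA + ACA + AComA).
#
# Each entry defines one intermediate lumped element.  The resistance
# chain name (R*) and the compliance chain name (C*) of the same index
# share a single evaluated element.  Children combine in the stated
# mode; a child's `factor` is its parallel multiplicity (fractional
# allowed).  `compliance_factor`, where present, encodes a published
# inconsistency: the resistance chain and the compliance chain of the
# same step used different branch counts (see entry R1: 16 LOFA copies
# for resistance, a single copy for compliance).  The self-consistent
# dialect drops these overrides.
#
# printed_resistance / printed_compliance are the reference values of
# the published tables (3 significant figures), kept for comparison
# only; evaluation always proceeds at full precision.
subtree: ica-distal
entries:
  - name: R1
    aliases: [C1]
    mode: parallel
    children:
      - {ref: B8}
      - {ref: B9}
      - {ref: B10, factor: 16, compliance_factor: 1}
    printed_resistance: 1.40e8
    printed_compliance: 1.67e-14
    note: B8, B9 and B10 in parallel for the distal end of M4
  - name: R2
    aliases: [C2]
    mode: series
    children: [{ref: R1}, {ref: B7}]
    printed_resistance: 2.01e9
    printed_compliance: 3.10e-15
    note: R1 and B7 in series for M4
  - name: R3
    aliases: [C3]
    mode: series
    children: [{ref: R2}, {ref: B6}, {ref: B4}]
    printed_resistance: 2.29e9
    printed_compliance: 2.54e-15
    note: R2, B6 and B4 in series
  - name: R4
    aliases: [C4]
    mode: parallel
    children: [{ref: R3, factor: 2}, {ref: B5}]
    printed_resistance: 1.34e8
    printed_compliance: 2.06e-14
    note: two copies of R3 and B5 in parallel at the M1-M2 intersection
  - name: R5
    aliases: [C5]
    mode: parallel
    children: [{ref: B3, factor: 9}]
    printed_resistance: 7.11e9
    printed_compliance: 5.94e-15
    note: 9 LLS branches in parallel
  - name: R6
    aliases: [C6]
    mode: parallel
    children: [{ref: R5}, {ref: B2}]
    printed_resistance: 5.55e7
    printed_compliance: 1.13e-13
    note: R5 and B2 in parallel for the M1 segment
  - name: R7
    aliases: [C7]
    mode: series
    children: [{ref: R4}, {ref: R6}]
    printed_resistance: 1.90e8
    printed_compliance: 1.75e-14
    note: R4 and R6 in series for the MCA branch
  - name: R8
    aliases: [C8]
    mode: series
    children: [{ref: B16}, {ref: B17}, {ref: B18}]
    printed_resistance: 5.39e9
    printed_compliance: 7.59e-15
    note: B16, B17 and B18 in series for the distal ACA segment
  - name: R9
    aliases: [C9]
    mode: parallel
    children: [{ref: B22, factor: 15}]
    printed_resistance: 7.51e7
    printed_compliance: 4.07e-14
    note: MOFA branches in parallel; published step text says 16 copies but
      the tabulated values correspond to the segment table's count of 15
  - name: R10
    aliases: [C10]
    mode: parallel
    children: [{ref: R9}, {ref: B23}, {ref: B12}]
    printed_resistance: 7.10e7
    printed_compliance: 4.75e-14
    note: R9, B23 and B12 in parallel for branches of the A2 segment
  - name: R11
    aliases: [C11]
    mode: parallel
    children: [{ref: R10}, {ref: B15}]
    printed_resistance: 3.63e7
    printed_compliance: 4.38e-13
    note: R10 and B15 in parallel for the A2 segment
  - name: R12
    aliases: [C12]
    mode: series
    children: [{ref: R11}, {ref: R8}]
    printed_resistance: 5.43e9
    printed_compliance: 7.46e-15
    note: R11 and R8 in series
  - name: R13
    aliases: [C13]
    mode: parallel
    children: [{ref: R12, factor: 2}]
    printed_resistance: 2.71e9
    printed_compliance: 1.49e-14
    note: two copies of R12 in parallel for segments from A2 to A5
  - name: R14
    aliases: [C14]
    mode: parallel
    children: [{ref: B24, factor: 7.6}]
    printed_resistance: 3.67e9
    printed_compliance: 8.36e-16
    note: 7.6 subcallosal-hypothalamic perforating branches in parallel
  - name: R15
    aliases: [C15]
    mode: parallel
    children: [{ref: R14}, {ref: B25}]
    printed_resistance: 1.40e9
    printed_compliance: 1.56e-15
    note: R14 and B25 in parallel for the AComA branches
  - name: R16
    aliases: [C16]
    mode: parallel
    children: [{ref: R15}, {ref: B19}]
    printed_resistance: 6.24e7
    printed_compliance: 6.16e-15
    note: R15 and B19 in parallel for the AComA segment
  - name: R17
    aliases: [C17]
    mode: parallel
    children: [{ref: R12}, {ref: R16}]
    printed_resistance: 6.17e7
    printed_compliance: 1.36e-14
    note: R12 and R16 in parallel at the A1-AComA-A2 intersection
  - name: R18
    aliases: [C18]
    mode: series
    children: [{ref: B14}, {ref: R17}]
    printed_resistance: 1.35e8
    printed_compliance: 1.22e-14
    note: B14 and R17 in series for the ACA segment
  - name: R19
    aliases: [C19]
    mode: parallel
    children: [{ref: R7}, {ref: R18}]
    printed_resistance: 5.89e7
    printed_compliance: 3.79e-14
    note: R7 and R18 for the distal ICA segment; the reference values match
      neither the series nor the parallel composition of their inputs and
      are flagged as an anomaly (parallel is the physical arrangement of
      the MCA and ACA trees and is what evaluation uses)
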