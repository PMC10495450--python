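# Parent -> children mapping of the carotid distal tree with per-edge
# multiplicities.  This encodes the anatomical arrangement behind the
# reduction chains; the chains themselves (recipes_*.yaml) remain the
# source of truth for reduction order, because the published arrangement
# places side branches in parallel with their trunk segment and reuses
# trunk segments along the chain in a way that a plain tree cannot
# express.  "junction:m1-m2" is an anatomical junction, not a segment.
edges:
  - {parent: B1, child: B2, multiplicity: 1}
  - {parent: B1, child: B14, multiplicity: 1}
  - {parent: B1, child: B28, multiplicity: 1}
  - {parent: B28, child: B26, multiplicity: 1}
  - {parent: B28, child: B27, multiplicity: 1}
  - {parent: B2, child: B3, multiplicity: 9}
  - {parent: B2, child: junction:m1-m2, multiplicity: 1}
  - {parent: junction:m1-m2, child: B5, multiplicity: 1}
  - {parent: junction:m1-m2, child: B4, multiplicity: 2}
  - {parent: B4, child: B6, multiplicity: 1}
  - {parent: B6, child: B7, multiplicity: 1}
  - {parent: B7, child: B8, multiplicity: 1}
  - {parent: B7, child: B9, multiplicity: 1}
  - {parent: B7, child: B10, multiplicity: 16}
  - {parent: B14, child: B19, multiplicity: 1}
  - {parent: B14, child: B15, multiplicity: 1}
  - {parent: B19, child: B24, multiplicity: 7.6}
  - {parent: B19, child: B25, multiplicity: 1}
  - {parent: B15, child: B22, multiplicity: 15}
  - {parent: B15, child: B23, multiplicity: 1}
  - {parent: B15, child: B12, multiplicity: 1}
  - {parent: B15, child: B16, multiplicity: 1}
  - {parent: B16, child: B17, multiplicity: 1}
  - {parent: B17, child: B18, multiplicity: 1}
  - {parent: B37, child: B38, multiplicity: 1}
  - {parent: B37, child: B29, multiplicity: 1}
  - {parent: B37, child: B30, multiplicity: 1}
  - {parent: B37, child: B31, multiplicity: 1}
  - {parent: B37, child: B32, multiplicity: 1}
  - {parent: B38, child: B33, multiplicity: 1}
  - {parent: B38, child: B34, multiplicity: 1}
  - {parent: B38, child: B35, multiplicity: 1}
  - {parent: B38, child: B36, multiplicity: 1}
# Segments present in the table but absent from the published reductions.
unreduced: [B11, B13, B20, B21]
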