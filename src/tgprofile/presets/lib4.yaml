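# Lib4: T26 backbone randomized at positions -1, +1, +2, +3 around the
# reactive Gln (0-based indices 0, 2, 3, 4; reactive Gln at index 1).
# Backbone residues 8-12 and all flanking DNA are synthetic stand-ins: the
# published construct table is not machine-readable.  Residues 1-7 (HQSYVDP)
# follow the T26 template.
name: Lib4
backbone_peptide: HQSYVDPWMLDH
reactive_index: 1
randomized_indices: [0, 2, 3, 4]
upstream_anchor: GGAGGTTCTAGTGCGAGC   # synthetic anchor
downstream_anchor: GGCAGCGGTTCTCACCAT # synthetic anchor
tags: {}
min_count_after: 100
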