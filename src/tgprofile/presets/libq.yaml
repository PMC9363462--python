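# LibQ: T26 backbone randomized only at the reactive Gln (index 1); used as
# the control library.  Before/after samples are pooled in one sequencing
# sample and distinguished by 10-nt in-read tags.
# Anchor and tag DNA are synthetic stand-ins (construct table not
# machine-readable); backbone residues 8-12 are literature-derived.
name: LibQ
backbone_peptide: HQSYVDPWMLDH
reactive_index: 1
randomized_indices: [1]
upstream_anchor: GGAGGTTCTAGTGCGAGC   # synthetic anchor
downstream_anchor: GGCAGCGGTTCTCACCAT # synthetic anchor
tags:
  before: ACGTACGTAC
  after: TGCATGCATG
min_count_after: 100
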