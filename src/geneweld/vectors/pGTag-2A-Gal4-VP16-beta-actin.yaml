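# Vector spec: pGTag-2A-Gal4-VP16-beta-actin
#
# The cargo below is a SYNTHETIC PLACEHOLDER of matching length class, not
# the deposited plasmid payload. Replace the `cargo` field with the coding
# sequence from the deposited map before designing real constructs; every
# other field (buffers, junction phase, scaffold layout) stays valid.
name: pGTag-2A-Gal4-VP16-beta-actin
description: >-
  Synthetic placeholder payload standing in for the deposited reporter
  cassette; marked for replacement with the real map.
cargo_is_synthetic_placeholder: true
cargo_junction_phase: 0
buffer5: AAA
buffer3: AAA
backbone_length: 400
scaffold_seed: 33
cargo: >-
  TCCGTTCCGGCCTTTGCAGGCAGAAATCAATTATGAAGGCACTAGTGCATGCAACCCAATCTGTGCCCAG
  TGTGCTCTAGGGATAAATGGCGAGCGGACAGCTAGGCCGATCAACGGCGTTGGCGGTTTGACTCGTCGGG
  CACCTAGGGAAGAACAGACCGCGCGGAGCAGCGTTCATCGAGCTAACGCTTGCAATGGGCTATAATGTGA
  AACGCACGACTGTGGCCCGATTCCGATCCGGTACTTCGGTACCAAATGCGCCCTTAATATACGAAGCGCT
  ATCCCGAATGGTAGTCCATCACATGATAGCGCTCGGACTAAAATGAAGGGACGTGGTTCCGGCGGGATAC
  AGGTAAGTTCTTTATTTGTAACGGAGCCCTCCCAGTGTAGGAACAGGAACGCAATTGTGGCCTTCTCCCA
  AAAGGATGGACTCTGTCTTGCTAATGAGGGACGGTACAGCCTAGCCCCCCTTCACCCTTTTATCGATCAC
  TACTGAGAGGGGGGGAACAGTATCCGGCGGCATGATCACCACTAATTCCACAGATACCACTGTGTCGACC
  TCCCGCGTCA
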