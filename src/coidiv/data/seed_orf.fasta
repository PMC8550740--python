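>synthetic_seed_orf synthetic 651-nt open reading frame (invertebrate mito code), simulation seed
AAATTTTATCCCAGGCACGTTTCAATTTCTCATAGACAATCTTCTTTTTCAGTATACTATTCAAATCTAT
ACGACTGTGACGTTGGCTCACACGCATTATTCAAGTCCCTAATTAAGGTGCTCAAAATATTGTCTCATCT
CTCAGAGATTTCTTATCGTAAAAATACCGTAAGATTATACAAAGCTTTGCAGAAATTTCAAGATTCCTAT
TATAACTTCCAACTGATTTATAGCATTAATCTTATCTGAGATTTGTGTATTTTTGAATATCCTCTATGGG
TATATAGGTGAATTTTCATTACCATTACAACGGTTCGATTTGTATTAACTTATACAACTGAAGTAAAGTG
TCTATACTCTATTAATTTAATATCTTATTACTTTCGAGAAGCTTCACAGTTTCTGTATTTAACACTTTTC
TTATTATTAGTTACATACTGACTCTTTATTCAATGTTGATTAATGAAAATCTATGTAAAATGGATACATT
TTATTTATCAGTTAATTATCTATCCTTTTATTCATGAGAAAGGTGTAACTTTATCCTACATAGTTATTCA
GTCGTTGTCTTACGTATTAACAGACCAAGGTAAATATGCTACCATGCTGATAGATAAATCTAGATTCCGT
CTGATAACCTTAAAAAATATC
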