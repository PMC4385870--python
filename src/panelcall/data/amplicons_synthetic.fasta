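>BRAF_V600
TGGTGTTAACCTTACTATACTCCCGCTCCGGGGTTTGGCTCATATGAACAAGTCTTTGCG
GTGATAAATGTAGCCAGTGAGCTTAGTTGGAGCAAGGGGTGCGGAAGCGCAACTCCGTCG
CGCGGGTAGCCAACTACTTAAGACCTAGGA
>EGFR_ex19
TTCTGTTGCAGATTAGAACTTGGGACTCAAGATTGCTGCCCTAAGCTATACTAGGCAGCT
AAGGAATTAAGAGAAGCAACATCTCCGCTTTATGCTTGAGAAAATCAACCCTTGTCACAT
ACATAGTGTTTGGGTCTTCCGTAAACAGGT
>EGFR_T790
GCTTGGCGAGTTCCGCGAAACACTTTGAGGTCAGCGCCATTCAGCGAAGAGCATGTTGTA
TCGTGTTGTTCAAACACCGATATGAACGAAAGAACCGTTGGTCGAGAATGCAATCTTTAA
GCTCAACGATCCGTCTCATTTTCAGGCGCG
>EGFR_L858
TACGAGTTGTCCAGCTCTAACACGGAAGGTTCACTCTGGAGCTAAGGTGCCCGGCAGAAC
TTGACTTGTCAAATTAGATAGAGTGCTCTTCGTAACATTCCGCAGGATGTTGCCGAAGTT
TACCGGAGGTGATAATCGAGCTGTTTATGC
>KRAS_G12
CGAATTGTCGACACCCCACTCGACTGAGTCATCTCCTAATTTAACGTTCTCACAGTAAAA
GGTGGTTACTTATTAACCAAACCCCGACGATTCTCTGAACGAGACATGTAAAGTGCTAAG
TCCGTCTGGGCGTCTTATCACACAGTTTAA
>PIK3CA_E542
GTTAGGCCGTTATCCGTAGATCTTATTTTTTGCTGGTGCCCAATTACTTGTCTTGACGCA
GTCGCTACGGCGCGTTACACAGATGCCGCAAGGTAAGGTAGTTCCCAGGGTGTATGCGAT
GATCAGAGTATGCAAACTGAGCTTTGAGCT
>PIK3CA_H1047
ACTGATCGGGCCAGCCAGTCCCATTGACATTCCTATTCTGTAGCTTCGCGTGTGCGCCAA
CAGCACGTGCCCTCAGTTCTTCCCCTCCTGAAATACGCAATCCTCTACTTGCTCGGCAGC
GGTTGAAGGTCCAAAGGACGCCCGTCCCAG
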