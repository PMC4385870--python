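# packaged sample barcode set: six 8-mers, minimum pairwise Hamming distance 4,
# supporting pools of six samples with 1-mismatch-tolerant demultiplexing
sample	barcode
S1	AATCGGGA
S2	CACTGAGA
S3	TTTGTCAG
S4	CGTCTACT
S5	AGCGTTTG
S6	TTAACGTC
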