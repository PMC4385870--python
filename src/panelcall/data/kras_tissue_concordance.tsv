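# KRAS status of tumor tissue in 19 metastatic colorectal cancer patients:
# multiplexed enrichment assay (assay_a) vs. conventional quantitative PCR (assay_b).
# Cell values are the detected allele (with abundance where reported), "WT",
# or "Not analyzed".
patient_id	assay_a_call	assay_b_call
SUCRC12	G12D (41%)	G12D
SUCRC14	G13D (0.04%)	WT
SUCRC16	G12D (6.5%)	G12D
SUCRC21	G12V (4.75%)	G12V
P004	G12S (24%)	G12S
P008	G12D (17%)	G12D
A007	G12D (36%)	G12D
SUCRC24	G13D (1.7%)	G13D
SUCRC17	WT	WT
SUCRC26	WT	WT
SUCRC27	WT	WT
SUCRC18	G13D (3.8%)	G13D
SUCRC13	G12D (18%)	G12D
SUCRC20	G12D (0.285%)	G12D
P001	WT	WT
SUCRC15	WT	WT
SUCRC19	WT	WT
SUCRC22	WT	Not analyzed
SUCRC23	WT	WT
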