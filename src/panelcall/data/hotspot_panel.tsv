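# 46-mutation ctDNA panel (BRAF, EGFR, KRAS, PIK3CA) with published per-mutation
# limits of detection (percent allele fraction).
# Coordinates are 0-based half-open offsets into the synthetic amplicon references
# (amplicons_synthetic.fasta); "-" in alt_allele denotes a pure deletion.
# Hotspot codon contexts are canonical cDNA; surrounding amplicon sequence is synthetic.
mutation_id	gene	amplicon_id	offset	ref_allele	alt_allele	published_lod_pct
BRAF V600D	BRAF	BRAF_V600	61	TG	AT	0.001
BRAF V600E (1799T>A)	BRAF	BRAF_V600	61	T	A	0.002
BRAF V600E (1799_1800TG>AA)	BRAF	BRAF_V600	61	TG	AA	0.001
BRAF V600K	BRAF	BRAF_V600	60	GT	AA	0.001
EGFR E746_A750del_2235	EGFR	EGFR_ex19	62	GGAATTAAGAGAAGC	-	0.001
EGFR E746_A750del_2236	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCA	-	0.001
EGFR E746_A750>IP	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCA	ATTCCT	0.001
EGFR E746_P753>VS	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACATCTCCG	GTTTCT	0.001
EGFR E746_S752>A	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACATCT	GCT	0.001
EGFR E746_S752>D	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACATCT	GAT	0.001
EGFR E746_S752>I	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACATCT	ATT	0.001
EGFR E746_S752>V	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACATCT	GTT	0.001
EGFR E746_T751>A	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACA	GCT	0.001
EGFR E746_T751>I	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACA	ATT	0.001
EGFR E746_T751>IP	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACA	ATTCCT	0.001
EGFR E746_T751>V	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACA	GTT	0.001
EGFR E746_T751>VA	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACA	GTTGCT	0.001
EGFR E746_T751del	EGFR	EGFR_ex19	63	GAATTAAGAGAAGCAACA	-	0.001
EGFR K745_E749del	EGFR	EGFR_ex19	60	AAGGAATTAAGAGAA	-	0.001
EGFR L747_A750>P_2238	EGFR	EGFR_ex19	66	TTAAGAGAAGCA	CCT	0.001
EGFR L747_A750>P_2239	EGFR	EGFR_ex19	66	TTAAGAGAAGCA	CCA	0.001
EGFR L747_E749del	EGFR	EGFR_ex19	66	TTAAGAGAA	-	0.001
EGFR L747_P753>Q	EGFR	EGFR_ex19	66	TTAAGAGAAGCAACATCTCCG	CAA	0.001
EGFR L747_P753>S	EGFR	EGFR_ex19	66	TTAAGAGAAGCAACATCTCCG	TCT	0.001
EGFR L747_S752>Q	EGFR	EGFR_ex19	66	TTAAGAGAAGCAACATCT	CAA	0.001
EGFR L747_S752del	EGFR	EGFR_ex19	66	TTAAGAGAAGCAACATCT	-	0.001
EGFR L747_T751>P	EGFR	EGFR_ex19	66	TTAAGAGAAGCAACA	CCT	0.001
EGFR L747_T751>Q	EGFR	EGFR_ex19	66	TTAAGAGAAGCAACA	CAA	0.001
EGFR L747_T751>S	EGFR	EGFR_ex19	66	TTAAGAGAAGCAACA	TCT	0.001
EGFR L747_T751del	EGFR	EGFR_ex19	66	TTAAGAGAAGCAACA	-	0.001
EGFR T790M	EGFR	EGFR_T790	61	C	T	0.020
EGFR L858R (2573T>G)	EGFR	EGFR_L858	61	T	G	0.001
EGFR L858R (2573_2574TG>GT)	EGFR	EGFR_L858	61	TG	GT	0.001
KRAS G12A	KRAS	KRAS_G12	61	G	C	0.003
KRAS G12C	KRAS	KRAS_G12	60	G	T	0.001
KRAS G12D	KRAS	KRAS_G12	61	G	A	0.020
KRAS G12R	KRAS	KRAS_G12	60	G	C	0.001
KRAS G12S	KRAS	KRAS_G12	60	G	A	0.018
KRAS G12V	KRAS	KRAS_G12	61	G	T	0.001
KRAS G13C	KRAS	KRAS_G12	63	G	T	0.008
KRAS G13D	KRAS	KRAS_G12	64	G	A	0.018
PIK3CA E542K	PIK3CA	PIK3CA_E542	60	G	A	0.023
PIK3CA E545K	PIK3CA	PIK3CA_E542	69	G	A	0.024
PIK3CA Q546K	PIK3CA	PIK3CA_E542	72	C	A	0.007
PIK3CA H1047L	PIK3CA	PIK3CA_H1047	61	A	T	0.001
PIK3CA H1047R	PIK3CA	PIK3CA_H1047	61	A	G	0.002
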