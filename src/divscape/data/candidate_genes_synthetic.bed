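# Candidate genes linked to avian bill/body size differentiation.
# Gene names, chromosome assignments (zebra finch nomenclature) and trait
# tags follow the published candidate list; the START/END coordinates are
# SYNTHETIC placeholders (the source table prints none) so that overlap
# machinery can be exercised — substitute real annotations for analyses.
# Columns: chrom, start (0-based), end, gene, trait.
chr1A	1000000	1040000	ALX1	bill
chr5	2000000	2035000	ALX4	bill
chr5	4000000	4028000	BMP4	bill
chr6	1500000	1560000	BMPR1A	bill
chr18	800000	830000	CACNA1G	bill
chr6	3200000	3255000	COL17A1	body
chr4A	900000	1060000	COL4A5	bill
chr7	2100000	2190000	COL6A3	body
chrZ	1200000	1290000	FGF10	bill
chr2	5000000	5003500	FOXC1	bill
chr5	6000000	6002000	GSC	bill
chr1A	3000000	3140000	HMGA2	bill
chr1A	5000000	5080000	IGF1	bill
chr2	7000000	7013000	INHBA	bill
chr1A	7000000	7300000	ITPR2	body
chr26	400000	470000	ITPR3	body
chr5	8000000	8900000	NELL1	bill
chr3	1000000	1010000	RDH14	bill
chr7	4000000	4190000	SATB2	bill
chr3	3000000	3004000	SIX2	bill
chr2	9000000	9260000	TRPS1	bill
chr2	11000000	11700000	VPS13B	bill
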