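gene_id	group	poly_ratio	tot_ratio	rr
ACVR1B	gene_expression	0.45	0.9	0.5
AKAP5	gene_expression	1.3	0.8	1.7
ASH1L	gene_expression	1.1	0.6	1.8
BRWD1	gene_expression	1.7	0.8	2.2
CBX5	gene_expression	0.9	2.0	0.5
CRTC1	gene_expression	0.9	1.4	0.6
DDX17	gene_expression	0.6	1.9	0.3
HDAC8	gene_expression	1.5	0.8	1.8
MLL5	gene_expression	1.7	0.7	2.4
NFE2L3	gene_expression	1.8	0.8	2.1
PHRF1	gene_expression	0.5	1.2	0.4
POLR3G	gene_expression	2.0	1.0	2.1
PRKACB	gene_expression	0.5	1.4	0.4
THRA	gene_expression	2.2	1.1	1.9
POLK	genome_integrity_dna_repair	2.2	0.9	2.3
REV1	genome_integrity_dna_repair	1.0	0.2	4.5
SMC5	genome_integrity_dna_repair	2.0	1.0	1.9
SMC6	genome_integrity_dna_repair	1.3	0.8	1.7
TOP1	genome_integrity_dna_repair	1.3	0.7	1.9
BHLHE41	cell_death_survival	2.6	0.8	3.2
CD47	cell_death_survival	0.9	0.5	1.7
DNASE1L3	cell_death_survival	1.8	1.0	1.8
FOXO3	cell_death_survival	0.5	1.0	0.5
HIPK2	cell_death_survival	1.5	0.9	1.8
TRIB3	cell_death_survival	1.2	0.5	2.4
FAM110B	cell_growth_proliferation	0.4	0.8	0.5
PTK7	cell_growth_proliferation	2.1	0.6	3.6
RUNX1	cell_growth_proliferation	0.9	1.4	0.6
TRAF4	cell_growth_proliferation	1.0	1.6	0.6
CDK6	cell_cycle_control	0.9	0.3	2.7
CRY2	cell_cycle_control	1.5	0.9	1.6
GSG2	cell_cycle_control	1.0	1.6	0.6
NDE1	cell_cycle_control	0.9	1.4	0.6
RECQL	cell_cycle_control	1.4	0.8	1.8
TPR	cell_cycle_control	1.8	0.7	2.5
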