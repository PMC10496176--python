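rsid	chrom	pos	effect_allele	other_allele	direction	source	label
rs0000001	1	10000	G	A	+	AD_gwas	LOC1
rs0000002	2	10100	G	A	+	AD_gwas	LOC2
rs0000003	3	10200	G	A	-	AD_gwas	LOC3
rs0000004	4	10300	G	A	+	AD_gwas	LOC4
rs0000005	5	10400	G	A	-	AD_gwas	LOC5
rs0000006	6	10500	G	A	+	AD_gwas	LOC6
rs0000007	7	10600	G	A	+	AD_gwas	LOC7
rs0000008	8	10700	G	A	-	AD_gwas	LOC8
rs0000009	9	10800	G	A	+	AD_gwas	LOC9
rs0000010	10	10900	G	A	+	AD_gwas	LOC10
rs0000011	11	11000	G	A	-	PD_gwas	LOC11
rs0000012	12	11100	G	A	+	PD_gwas	LOC12
rs0000013	13	11200	G	A	+	PD_gwas	LOC13
rs0000014	14	11300	G	A	-	PD_gwas	LOC14
rs0000015	15	11400	G	A	+	PD_gwas	LOC15
rs0000016	16	11500	G	A	+	PD_gwas	LOC16
rs0000017	17	11600	G	A	-	PD_gwas	LOC17
rs0000018	18	11700	G	A	+	PD_gwas	LOC18
rs0000019	19	11800	G	A	+	PD_gwas	LOC19
rs0000020	20	11900	G	A	-	PD_gwas	LOC20
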