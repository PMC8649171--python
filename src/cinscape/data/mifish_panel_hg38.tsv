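# 20-probe multiplex interphase FISH panel: one centromere probe (CCP10) plus 19
# gene loci, hybridised as four panels of five probes each. Anchor positions are
# representative hg38 gene/centromere coordinates used only to place each probe in
# a genome bin. The RB1 cytoband is recorded as 13q14.2 (the source table's
# "13.14.2" is a typographical variant).
name	cytoband	chromosome	position	group
CCP10	10p11.1	chr10	39800000	1
COX2	1q31.1	chr1	186671791	1
PIK3CA	3q26.32	chr3	179148114	1
FBXW7	4q31.3	chr4	152320544	1
CCNB1	5q13.2	chr5	69167135	1
DBC2	8p21.3	chr8	22987632	2
MYC	8q24.21	chr8	127735434	2
CDKN2A	9p21.3	chr9	21967752	2
PTEN	10q23.31	chr10	87863113	2
CCND1	11q13.3	chr11	69641156	2
KRAS	12p12.1	chr12	25205246	3
RB1	13q14.2	chr13	48303748	3
CDH1	16q22.1	chr16	68737292	3
TP53	17p13.1	chr17	7668421	3
NF1	17q11.2	chr17	31094927	3
HER2	17q12	chr17	39688094	4
SMAD4	18q21.2	chr18	51028394	4
CCNE1	19q12	chr19	29811898	4
ZNF217	20q13.2	chr20	53569866	4
NF2	22q12.2	chr22	29603556	4
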