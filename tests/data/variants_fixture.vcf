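##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=SRP,Number=1,Type=Integer,Description="Simple repeat periodicity (0 = none)">
##INFO=<ID=HPL,Number=1,Type=Integer,Description="Homopolymer length at site">
##INFO=<ID=DNL,Number=1,Type=Integer,Description="Dinucleotide repeat length at site">
##INFO=<ID=RMSK,Number=0,Type=Flag,Description="Overlaps annotated repeat or segmental duplication">
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	S1	S2
chrF	500001	v1	A	G	.	PASS	MQ=55;SRP=0;HPL=2;DNL=0	AD	15,15	30,0
chrF	550001	v2	C	T	.	PASS	MQ=35;SRP=0;HPL=2;DNL=0	AD	15,15	30,0
chrF	600001	v3	G	A	.	PASS	MQ=40;SRP=0;HPL=3;DNL=0	AD	15,15	30,0
chrF	650001	v4	T	C	.	PASS	MQ=55;SRP=0;HPL=9;DNL=0	AD	15,15	30,0
chrF	700001	v5	A	G	.	PASS	MQ=55;SRP=0;HPL=8;DNL=0	AD	15,15	30,0
chrF	750001	v6	C	T	.	PASS	MQ=55;SRP=0;HPL=2;DNL=15	AD	15,15	30,0
chrF	800001	v7	G	A	.	PASS	MQ=55;SRP=0;HPL=2;DNL=14	AD	15,15	30,0
chrF	850001	v8	T	C	.	PASS	MQ=55;SRP=8;HPL=2;DNL=0	AD	15,15	30,0
chrF	900001	v9	A	G	.	PASS	MQ=55;SRP=9;HPL=2;DNL=0	AD	15,15	30,0
chrF	950001	v10	C	T	.	PASS	MQ=55;SRP=0;HPL=1;DNL=0	AD	15,15	30,0
chrF	1000001	v11	G	A	.	PASS	MQ=55;SRP=0;HPL=2;DNL=0;RMSK	AD	15,15	30,0
chrF	100001	v12	A	G	.	PASS	MQ=55;SRP=0;HPL=2;DNL=0	AD	15,15	30,0
chrF	103001	v13	C	T	.	PASS	MQ=55;SRP=0;HPL=2;DNL=0	AD	15,15	30,0
chrF	106001	v14	G	A	.	PASS	MQ=55;SRP=0;HPL=2;DNL=0	AD	15,15	30,0
chrF	109001	v15	T	C	.	PASS	MQ=55;SRP=0;HPL=2;DNL=0	AD	15,15	30,0
chrF	200001	v16	A	G	.	PASS	MQ=55;SRP=0;HPL=2;DNL=0	AD	30,0	15,15
chrF	204001	v17	C	T	.	PASS	MQ=55;SRP=0;HPL=2;DNL=0	AD	30,0	15,15
chrF	208001	v18	G	A	.	PASS	MQ=55;SRP=0;HPL=2;DNL=0	AD	30,0	15,15
chrF	1050001	v19	T	C	.	PASS	MQ=30;SRP=0;HPL=10;DNL=0	AD	15,15	30,0
chrF	1100001	v20	A	G	.	PASS	MQ=55;SRP=0;HPL=2;DNL=0	AD	30,0	1,29
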