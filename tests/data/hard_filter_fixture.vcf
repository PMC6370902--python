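##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">
##INFO=<ID=QD,Number=1,Type=Float,Description="QD site annotation">
##INFO=<ID=FS,Number=1,Type=Float,Description="FS site annotation">
##INFO=<ID=MQ,Number=1,Type=Float,Description="MQ site annotation">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQRankSum site annotation">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="ReadPosRankSum site annotation">
##INFO=<ID=SOR,Number=1,Type=Float,Description="SOR site annotation">
##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="HaplotypeScore site annotation">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	SAMPLE
1	100	.	A	G	.	.	DP=30;QD=1.5;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0;HaplotypeScore=2.0	GT	0/1
1	200	.	C	T	.	.	DP=30;QD=25.0;FS=70.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0;HaplotypeScore=2.0	GT	0/1
1	300	.	G	A	.	.	DP=30;QD=25.0;FS=1.0;MQ=30.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0;HaplotypeScore=2.0	GT	0/1
1	400	.	T	C	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=-13.0;ReadPosRankSum=0.3;SOR=1.0;HaplotypeScore=2.0	GT	0/1
1	500	.	A	C	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=-9.0;SOR=1.0;HaplotypeScore=2.0	GT	0/1
1	600	.	C	G	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0;HaplotypeScore=14.0	GT	0/1
1	700	.	G	T	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=4.0;HaplotypeScore=2.0	GT	0/1
1	800	.	AT	A	.	.	DP=30;QD=1.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0	GT	0/1
1	900	.	A	AT	.	.	DP=30;QD=25.0;FS=250.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0	GT	0/1
1	1000	.	GCA	G	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=-25.0;SOR=1.0	GT	0/1
1	1100	.	T	TG	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=12.0	GT	0/1
1	1200	.	A	G	.	.	DP=30;QD=2.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0;HaplotypeScore=2.0	GT	0/1
1	1300	.	C	T	.	.	DP=30;QD=25.0;FS=60.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0;HaplotypeScore=2.0	GT	0/1
1	1400	.	G	A	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=3.0;HaplotypeScore=2.0	GT	0/1
1	1500	.	T	C	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0;HaplotypeScore=13.0	GT	0/1
1	1600	.	CT	C	.	.	DP=30;QD=2.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0	GT	0/1
1	1700	.	G	GA	.	.	DP=30;QD=25.0;FS=100.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0	GT	0/1
1	1800	.	ATT	A	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=5.0	GT	0/1
1	1900	.	C	CG	.	.	DP=30;QD=25.0;FS=1.0;MQ=35.0;MQRankSum=0.5;ReadPosRankSum=-12.0;SOR=1.0	GT	0/1
1	2000	.	A	T	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0;HaplotypeScore=2.0	GT	0/1
1	2100	.	TG	T	.	.	DP=30;QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;SOR=1.0	GT	0/1
1	2200	.	C	A	.	.	DP=30	GT	0/1
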