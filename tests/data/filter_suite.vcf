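##fileformat=VCFv4.2
##contig=<ID=c1,length=2000>
##FILTER=<ID=LowQual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	A	B
c1	100	.	A	G	.	PASS	.	GT:DP:AD	0/1:20:10,10	0/0:20:20,0
c1	150	.	AT	A	.	PASS	.	GT:DP:AD	0/1:20:10,10	0/0:20:20,0
c1	200	.	C	T	.	LowQual	.	GT:DP:AD	0/1:20:10,10	0/0:20:20,0
c1	250	.	G	A,T	.	PASS	.	GT:DP:AD	1/2:20:0,10,10	0/0:20:20,0,0
c1	300	.	T	C	.	PASS	.	GT:DP:AD	0/1:10:5,5	0/1:9:5,4
c1	350	.	A	C	.	PASS	.	GT:DP:AD	0/1:9:4,5	0/1:9:5,4
c1	400	.	G	T	.	PASS	.	GT:DP:AD	0/1:20:6,14	0/1:20:5,15
c1	450	.	C	A	.	PASS	.	GT:DP:AD	1/1:20:0,20	0/0:20:20,0
c1	500	.	T	A	.	PASS	.	GT:DP:AD	0/1:20:.	0/0:20:20,0
c1	1000	.	A	C	.	PASS	.	GT:DP:AD	0/1:20:10,10	0/0:20:20,0
c1	1201	.	G	C	.	PASS	.	GT:DP:AD	0/1:20:10,10	0/0:20:20,0
c1	1300	.	C	G	.	PASS	.	GT:DP:AD	0/1:40:12,28	0/0:40:40,0
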