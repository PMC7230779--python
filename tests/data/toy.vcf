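##fileformat=VCFv4.2
##contig=<ID=scaffold1,length=10000>
##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type annotation">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	I1	I2	I3	I4	I5	I6	I7	I8	I9	I10
scaffold1	100	.	A	T	50	PASS	TYPE=snp	GT:DP	0/1:20	0/1:20	0/1:20	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
scaffold1	200	.	A	T,G	50	PASS	TYPE=snp	GT:DP	0/1:20	0/2:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
scaffold1	300	.	C	G	50	PASS	TYPE=snp	GT:DP	0/1:5	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
scaffold1	400	.	G	A	50	PASS	TYPE=snp	GT:DP	./.:0	./.:0	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20	0/0:20
scaffold1	500	.	T	C	50	PASS	TYPE=snp	GT:DP	1/1:20	0/1:20	0/1:20	0/0:20	0/0:20	0/0:20	0/1:20	0/0:20	0/0:20	0/0:20
scaffold1	600	.	A	G	50	PASS	TYPE=snp	GT:DP	0/1:20	0/0:20	0/1:20	0/0:20	0/1:20	0/0:20	0/0:20	0/0:20	0/0:20	./.:0
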