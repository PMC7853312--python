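##fileformat=VCFv4.2
##source=hand-written toy panel for filter attrition checks
##contig=<ID=scaffold_A,length=100000>
##contig=<ID=scaffold_B,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	s1	s2	s3	s4	s5	s6
scaffold_A	100	.	A	G	.	PASS	.	GT:PL:DP	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10	0/1:60,0,60:10	0/0:0,60,120:10	0/0:0,60,120:10
scaffold_A	500	.	C	T	.	PASS	.	GT:PL:DP	0/0:0,60,120:10	./.:0,0,0:0	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10	0/1:60,0,60:10
scaffold_A	900	.	G	A	.	PASS	.	GT:PL:DP	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10
scaffold_A	950	.	G	A,T	.	PASS	.	GT:PL:DP	0/0:0,60,120,60,120,120:10	0/0:0,60,120,60,120,120:10	0/0:0,60,120,60,120,120:10	0/0:0,60,120,60,120,120:10	0/0:0,60,120,60,120,120:10	0/0:0,60,120,60,120,120:10
scaffold_A	1500	.	T	C	.	PASS	.	GT:PL:DP	0/1:60,0,60:10	0/1:60,0,60:10	0/1:60,0,60:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10
scaffold_A	2500	.	A	C	.	PASS	.	GT:PL:DP	0/1:60,0,60:10	0/1:60,0,60:10	0/1:60,0,60:10	0/1:60,0,60:10	0/1:60,0,60:10	0/1:60,0,60:10
scaffold_A	2600	.	C	G	.	PASS	.	GT:PL:DP	1/1:120,60,0:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10
scaffold_B	100	.	T	A	.	PASS	.	GT:PL:DP	0/0:0,60,120:10	0/1:60,0,60:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10
scaffold_B	150	.	G	C	.	PASS	.	GT:PL:DP	./.:0,0,0:0	0/0:0,60,120:10	./.:0,0,0:0	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10
scaffold_B	800	.	A	T	.	PASS	.	GT:PL:DP	1/1:120,60,0:10	1/1:120,60,0:10	1/1:120,60,0:10	1/1:120,60,0:10	1/1:120,60,0:10	1/1:120,60,0:10
scaffold_B	60000	.	C	A	.	PASS	.	GT:PL:DP	0/1:60,0,60:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10	0/0:0,60,120:10
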