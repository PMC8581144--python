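sample	group	svtype	chrom1	pos1_kb	chrom2	pos2_kb	chrom3	pos3_kb	size_kb	zygosity	truncated_genes	deleted_genes	process
P493-1	P493	inversion	1	6150.1	1	7404.1			1254.0	heterozygous	2	0	P493-1.a
P493-1	P493	deletion	3	6848.9	3	6868.1			19.2	homozygous	0	4	P493-1.b
P493-4	P493	deletion	3	2675.7	3	2742.3			66.6	heterozygous	2	20	P493-4.a
P493-5	P493	inversion	5	24769.6	5	25113.1			343.6	heterozygous	2	0	P493-5.a
P493-6	P493	deletion	3	16383.6	3	16559.3			176.7	heterozygous	0	47	P493-6.a
P787-1	P787	deletion	5	22897.2	5	22909.6			12.4	heterozygous	2	4	P787-1.a
P787-2	P787	inversion	4	8941.6	4	9211.0			269.2	heterozygous	0	0	P787-2.a
P787-2	P787	deletion	5	19413.2	5	19416.9			3.7	homozygous	1	1	P787-2.b
P787-3	P787	inversion	1	28507.0	1	29353.5			846.4	heterozygous	1	0	P787-3.a
P787-3	P787	inversion	2	12656.5	2	13216.5			560.0	heterozygous	1	0	P787-3.b
P787-3	P787	deletion	2	13166.0	2	13635.5			469.5	heterozygous	1	127	P787-3.c
P787-3	P787	translocation	2	2385.0	5	5354.5	5	6229.2	874.7	heterozygous	0	0	P787-3.d
P787-3	P787	inversion	5	16585.1	5	16660.3			75.1	heterozygous	1	0	P787-3.e
P787-4	P787	deletion	2	3072.1	2	3072.9			0.8	heterozygous	1	0	P787-4.a
P787-5	P787	inversion	5	24670.0	5	25022.4			352.4	heterozygous	1	0	P787-5.a
P787-6	P787	inversion	1	6490.1	1	8080.0			1589.9	heterozygous	1	0	P787-6.a
P787-6	P787	inversion	1	13595.3	1	13793.2			197.9	heterozygous	0	0	P787-6.b
P787-6	P787	inversion	4	7403.4	4	11612.1			4208.7	heterozygous	1	0	P787-6.c
P787-6	P787	inversion	4	11612.1	4	11612.9			0.7	heterozygous	0	0	P787-6.c
P787-6	P787	deletion	5	12250.2	5	12250.7			0.5	heterozygous	0	0	P787-6.d
P787-6	P787	translocation	1	24564.6	4	13145.3				heterozygous	2	0	P787-6.e
P995-1	P995	inversion	3	14553.8	3	15034.2			480.4	homozygous	1	0	P995-1.a
P995-1	P995	inversion	4	9114.6	4	9436.6			322.0	heterozygous	1	0	P995-1.b
P995-1	P995	inversion	4	9114.6	4	9718.0			603.4	heterozygous	1	80	P995-1.b
P995-1	P995	translocation	4	2320.8	5	21780.2				heterozygous	0	0	P995-1.c
P995-2	P995	deletion	2	6777.8	2	6799.4			21.6	heterozygous	0	2	P995-2.a
P995-4	P995	inversion	2	8396.2	2	9163.3			767.1	heterozygous	1	0	P995-4.a
P995-4	P995	inversion	3	13989.4	3	18192.8			4203.4	homozygous	0	0	P995-4.b
P995-4	P995	inversion	4	3154.6	4	3363.6			209.0	heterozygous	0	0	P995-4.c
P995-4	P995	inversion	4	14934.7	4	15407.4			472.7	heterozygous	1	0	P995-4.d
P995-4	P995	inversion	5	10530.7	5	10863.8			333.1	heterozygous	0	0	P995-4.e
P995-4	P995	inversion	5	20353.5	5	20843.1			489.6	homozygous	1	0	P995-4.f
P995-4	P995	deletion	5	20983.7	5	20986.5			2.7	homozygous	0	0	P995-4.g
P995-4	P995	deletion	5	22528.3	5	22549.4			21.2	homozygous	1	4	P995-4.h
P995-4	P995	translocation	5	13499.0	scaffold15_Contig624	84.6				heterozygous	1	0	P995-4.i
P995-5	P995	inversion	1	320.3	1	723.9			403.6	heterozygous	2	0	P995-5.a
P995-6	P995	translocation	1	2866.4	5	4681.7			3.6	heterozygous	0	0	P995-6.a
G900-1	G900	inversion	1	11198.8	1	11203.4			5.6	homozygous	2	0	G900-1.a
G900-1	G900	translocation	3	1725.5	4	8909.7				homozygous	1	0	G900-1.b
G900-2	G900	inversion	3	2352.9	3	2353.6			0.7	homozygous	0	0	G900-2.a
G900-5	G900	deletion	2	14586.0	2	14599.6			13.6	heterozygous	1	1	G900-5.a
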