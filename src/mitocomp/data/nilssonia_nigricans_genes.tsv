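name	category	strand	start	end	start2	end2	anticodon	start_codon	stop_codon	size
trnF	tRNA	H	59	128	.	.	GAA	.	.	70
rrnS	rRNA	H	129	1110	.	.	.	.	.	982
trnV	tRNA	H	1109	1178	.	.	TAC	.	.	70
rrnL	rRNA	H	1179	2789	.	.	.	.	.	1611
trnL2	tRNA	H	2790	2865	.	.	TAA	.	.	76
nad1	PCG	H	2879	3823	.	.	.	ATA	A	945
trnI	tRNA	H	3832	3901	.	.	GAT	.	.	70
trnQ	tRNA	L	3901	3971	.	.	TTG	.	.	71
trnM	tRNA	H	3971	4039	.	.	CAT	.	.	69
nad2	PCG	H	4040	5068	.	.	.	ATG	A	1029
trnW	tRNA	H	5082	5156	.	.	TCA	.	.	75
trnA	tRNA	L	5161	5229	.	.	TGC	.	.	69
trnN	tRNA	L	5231	5304	.	.	GTT	.	.	74
trnC	tRNA	L	5338	5403	.	.	GCA	.	.	66
trnY	tRNA	L	5404	5471	.	.	GTA	.	.	68
cox1	PCG	H	5476	7008	.	.	.	ATT	A	1533
trnS2	tRNA	L	7013	7083	.	.	TGA	.	.	71
trnD	tRNA	H	7084	7152	.	.	GTC	.	.	69
cox2	PCG	H	7153	7833	.	.	.	ATG	T	681
trnK	tRNA	H	7841	7916	.	.	TTT	.	.	76
atp8	PCG	H	7918	8076	.	.	.	ATG	A	159
atp6	PCG	H	8073	8753	.	.	.	ATG	TAA	681
cox3	PCG	H	8756	9538	.	.	.	ATG	T	783
trnG	tRNA	H	9540	9609	.	.	TCC	.	.	70
nad3	PCG	H	9610	9958	.	.	.	ATG	AGA	348
trnR	tRNA	H	9960	10030	.	.	TCG	.	.	71
nad4l	PCG	H	10032	10325	.	.	.	ATG	TAA	294
nad4	PCG	H	10322	11692	.	.	.	ATG	C	1371
trnH	tRNA	H	11703	11772	.	.	GTG	.	.	70
trnS1	tRNA	H	11773	11834	.	.	GCT	.	.	62
trnL1	tRNA	H	11834	11905	.	.	TAG	.	.	72
nad5	PCG	H	11906	13681	.	.	.	ATG	TAA	1776
nad6	PCG	L	13683	14204	.	.	.	ATG	T	522
trnE	tRNA	L	14205	14272	.	.	TTC	.	.	68
cytb	PCG	H	14282	15409	.	.	.	ATC	A	1128
trnT	tRNA	H	15419	15492	.	.	TGT	.	.	74
trnP	tRNA	L	15495	15564	.	.	TGG	.	.	70
CR	CR	H	15565	16796	1	58	.	.	.	1290
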