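pair	block	chrom	start	stop	length	genes	tandem_duplicates	lethal_genes	tes_other	syntenic_genes	deleted
1	271	3	16,628,704	16,753,190	124,486	27	19	0	8	7	yes
1	488	5	24,228,178	24,282,157	53,979	15	5	2	1	7	no
2	438	5	10,030,493	10,281,880	251,387	16	3	0	34	7	yes
2	215	3	1,318,096	1,367,508	49,412	17	0	3	0	7	no
3	268	3	14,954,587	15,645,446	690,859	60	6	0	112	11	yes
3	425	5	7,002,453	7,166,904	164,451	29	2	4	10	11	no
4	324	4	6,415,287	6,567,629	152,342	32	14	0	4	12	yes
4	66	1	11,858,251	12,073,833	215,582	46	13	2	12	12	no
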