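chr1	0	123400000	p	gneg
chr1	123400000	248956422	q	gneg
chr2	0	93900000	p	gneg
chr2	93900000	242193529	q	gneg
chr3	0	90900000	p	gneg
chr3	90900000	198295559	q	gneg
chr4	0	50000000	p	gneg
chr4	50000000	190214555	q	gneg
chr5	0	48800000	p	gneg
chr5	48800000	181538259	q	gneg
chr6	0	59800000	p	gneg
chr6	59800000	170805979	q	gneg
chr7	0	60100000	p	gneg
chr7	60100000	159345973	q	gneg
chr8	0	45200000	p	gneg
chr8	45200000	145138636	q	gneg
chr9	0	43000000	p	gneg
chr9	43000000	138394717	q	gneg
chr10	0	39800000	p	gneg
chr10	39800000	133797422	q	gneg
chr11	0	53400000	p	gneg
chr11	53400000	135086622	q	gneg
chr12	0	35500000	p	gneg
chr12	35500000	133275309	q	gneg
chr13	0	17700000	p	gneg
chr13	17700000	114364328	q	gneg
chr14	0	17200000	p	gneg
chr14	17200000	107043718	q	gneg
chr15	0	19000000	p	gneg
chr15	19000000	101991189	q	gneg
chr16	0	36800000	p	gneg
chr16	36800000	90338345	q	gneg
chr17	0	25100000	p	gneg
chr17	25100000	83257441	q	gneg
chr18	0	18500000	p	gneg
chr18	18500000	80373285	q	gneg
chr19	0	26200000	p	gneg
chr19	26200000	58617616	q	gneg
chr20	0	28100000	p	gneg
chr20	28100000	64444167	q	gneg
chr21	0	12000000	p	gneg
chr21	12000000	46709983	q	gneg
chr22	0	15000000	p	gneg
chr22	15000000	50818468	q	gneg
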