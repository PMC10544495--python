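name	length	centromere	is_autosome
chr1	248956422	123000000	1
chr2	242193529	94000000	1
chr3	198295559	91000000	1
chr4	190214555	50000000	1
chr5	181538259	48000000	1
chr6	170805979	60000000	1
chr7	159345973	60000000	1
chr8	145138636	45000000	1
chr9	138394717	43000000	1
chr10	133797422	40000000	1
chr11	135086622	53000000	1
chr12	133275309	36000000	1
chr13	114364328	18000000	1
chr14	107043718	17000000	1
chr15	101991189	19000000	1
chr16	90338345	37000000	1
chr17	83257441	25000000	1
chr18	80373285	18000000	1
chr19	58617616	26000000	1
chr20	64444167	28000000	1
chr21	46709983	12000000	1
chr22	50818468	15000000	1
chrX	156040895	61000000	0
chrY	57227415	10000000	0
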