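allele	haplotypes
*1	189
*2	57
*4	7
*5	5
*10	74
*35	3
*41	27
*43	1
*71	36
*167	1
*168	1
*169	2
*170	1
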