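position	ref	alt	background_allele	carriers
4818	G	A	*4	2
6528	G	A	*41	19
7058	A	C	*4	1
7061	G	C	*1	1
7238	G	C	*1	2
8376	G	A	*1	1
8406		AGCACC	*1	2
8887	C	T	*2	2
9021	A	G	*41	1
9414	C	T	*10	1
9464	G	A	*10	1
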