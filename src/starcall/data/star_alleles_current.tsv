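#reference=CYP2D6_synthetic
allele	suballele	position	ref	alt	function	activity	structural
*1					normal	1	none
*1	*1.050	7061	G	C	normal	1	none
*1	*1.051	7238	G	C	normal	1	none
*1	*1.052	8376	G	A	normal	1	none
*1	*1.053	8406		AGCACC	normal	1	none
*2		5834	C	T	normal	1	none
*2		8208	G	C	normal	1	none
*2	*2.031	8887	C	T	normal	1	none
*4		5730	C	T	none	0	none
*4		6422	G	A	none	0	none
*4		7725	A	G	none	0	none
*4	*4.032	7058	A	C	none	0	none
*4	*4.033	4818	G	A	none	0	none
*5					none	0	whole_gene_deletion
*10		5065	C	T	decreased	0.25	none
*10		8591	G	A	decreased	0.25	none
*10	*10.061	9414	C	T	decreased	0.25	none
*10	*10.062	9464	G	A	decreased	0.25	none
*35		5112	G	A	normal	1	none
*35		5834	C	T	normal	1	none
*35		8208	G	C	normal	1	none
*41		6177	G	A	decreased	0.5	none
*41		8020	C	T	decreased	0.5	none
*41	*41.006	6528	G	A	decreased	0.5	none
*41	*41.007	9021	A	G	decreased	0.5	none
*43		5522	G	A	uncertain		none
*71		5168	G	A	uncertain		none
*167		6071	A	G	unknown		none
*168		6947	G	A	unknown		none
*169		8849	G	C	unknown		none
*170		8934	C	T	unknown		none
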