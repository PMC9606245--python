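#reference=CYP2D6_synthetic
allele	suballele	position	ref	alt	function	activity	structural
*1					normal	1	none
*2		5834	C	T	normal	1	none
*2		8208	G	C	normal	1	none
*4		5730	C	T	none	0	none
*4		6422	G	A	none	0	none
*4		7725	A	G	none	0	none
*5					none	0	whole_gene_deletion
*10		5065	C	T	decreased	0.25	none
*10		8591	G	A	decreased	0.25	none
*35		5112	G	A	normal	1	none
*35		5834	C	T	normal	1	none
*35		8208	G	C	normal	1	none
*41		6177	G	A	decreased	0.5	none
*41		8020	C	T	decreased	0.5	none
*43		5522	G	A	uncertain		none
*56		6230	G	T	none	0	none
*56		9414	C	T	none	0	none
*59		7150	T	G	decreased	0.5	none
*59		9464	G	A	decreased	0.5	none
*71		5168	G	A	uncertain		none
*136		5301	T	C	none	0	none
*136		7866	G	A	none	0	none
*136		8934	C	T	none	0	none
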