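position	ref	alt	rsid	consequence	aa_change	sift_score	sift_label	polyphen_score	polyphen_label	designation
4818	G	A	rs372204775	noncoding						*4.033
6071	A	G		missense	Gln>Arg	0.02	deleterious	0.476	possibly_damaging	*167.001
6528	G	A	rs369508051	noncoding						*41.006
6947	G	A	rs755518310	missense	Glu>Lys	0.01	deleterious	0.043	benign	*168.001
7058	A	C	rs564994275	noncoding						*4.032
7061	G	C	rs778008161	noncoding						*1.050
7238	G	C		noncoding						*1.051
8376	G	A	rs376909251	noncoding						*1.052
8406		AGCACC		noncoding						*1.053
8849	G	C	rs1602566413	missense	Val>Leu	0.03	deleterious	0.67	possibly_damaging	*169.001
8887	C	T	rs1037093492	synonymous	Arg>Arg				no_effect	*2.031
9021	A	G	rs769045995	noncoding						*41.007
8934	C	T		missense	Gly>Glu	0.01	deleterious	0.81	possibly_damaging	*170.001
9414	C	T		noncoding						*10.061
9464	G	A		noncoding						*10.062
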