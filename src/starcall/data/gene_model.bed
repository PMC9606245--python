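CYP2D6_synthetic	4000	5000	promoter
CYP2D6_synthetic	5000	5200	exon1
CYP2D6_synthetic	5200	5900	intron1
CYP2D6_synthetic	5900	6100	exon2
CYP2D6_synthetic	6100	6700	intron2
CYP2D6_synthetic	6700	6850	exon3
CYP2D6_synthetic	6850	6900	intron3
CYP2D6_synthetic	6900	7000	exon4
CYP2D6_synthetic	7000	7300	intron4
CYP2D6_synthetic	7300	7450	exon5
CYP2D6_synthetic	7450	7600	intron5
CYP2D6_synthetic	7600	7750	exon6
CYP2D6_synthetic	7750	7900	intron6
CYP2D6_synthetic	7900	8050	exon7
CYP2D6_synthetic	8050	8500	intron7
CYP2D6_synthetic	8500	8960	exon8
CYP2D6_synthetic	8960	9100	intron8
CYP2D6_synthetic	9100	9300	exon9
CYP2D6_synthetic	9300	9700	downstream
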