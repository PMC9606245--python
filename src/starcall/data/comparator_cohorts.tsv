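cohort	allele	count	total	reconstructed
ni_vanuatu	*1	447	556	yes
ni_vanuatu	*2	38	556	yes
ni_vanuatu	*10	16	556	yes
ni_vanuatu	*71	5	556	yes
solomon_islands	*71	35	600	yes
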