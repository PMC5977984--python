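gene_a	gene_b	combined_score
GENE01	GENE04	0.6626271847864026
GENE01	GENE02	0.823969608000304
GENE02	GENE04	0.7635439404002198
GENE03	GENE05	0.7296751844878168
GENE05	GENE06	0.7242210670083779
GENE03	GENE06	0.8766813860486427
GENE01	GENE05	0.9168003428370108
GENE08	GENE10	0.1894908302066708
GENE07	GENE10	0.3759550481611835
GENE10	GENE11	0.20164373599412858
GENE07	GENE09	0.16789991705302104
GENE08	GENE09	0.10385214471004198
GENE09	GENE12	0.15861927996146621
GENE08	GENE12	0.3623872171576539
GENE11	GENE12	0.20353017360018766
GENE09	GENE10	0.2690132123507637
GENE07	GENE11	0.3087984610401351
GENE07	GENE08	0.16836759367220733
GENE09	GENE11	0.24099127372185097
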