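mirna_id	gene_id	source
miR-1	GENE01	B
miR-1	GENE02	B
miR-1	GENE03	B
miR-2	GENE04	B
miR-2	GENE05	B
miR-2	GENE06	B
miR-8	GENE05	B
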