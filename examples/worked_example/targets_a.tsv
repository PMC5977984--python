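mirna_id	gene_id	source
miR-1	GENE01	A
miR-1	GENE02	A
miR-1	GENE03	A
miR-2	GENE04	A
miR-2	GENE05	A
miR-2	GENE06	A
miR-4	GENE12	A
miR-8	GENE10	A
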