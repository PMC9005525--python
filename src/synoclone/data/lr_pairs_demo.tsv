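ligand_gene	receptor_gene	category
CXCL9	CXCR3	chemokine
CXCL10	CXCR3	chemokine
CXCL11	CXCR3	chemokine
CXCL16	CXCR6	chemokine
CX3CL1	CX3CR1	chemokine
CCL5	CCR5	chemokine
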