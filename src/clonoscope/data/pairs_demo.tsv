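pair_id	ligand_gene	receptor_gene
CXCL12_CXCR4	CXCL12	CXCR4
CCL5_CCR4	CCL5	CCR4
SELL_CD34	SELL	CD34
MIF_CD74	MIF	CD74
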