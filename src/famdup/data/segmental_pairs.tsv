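gene_a	gene_b
AcPRX59	AcPRX16
AcPRX58	AcPRX46
AcPRX46	AcPRX15
AcPRX59	AcPRX15
AcPRX30	AcPRX12
AcPRX32	AcPRX37
AcPRX30	AcPRX37
AcPRX22	AcPRX41
AcPRX20	AcPRX18
AcPRX33	AcPRX9
AcPRX48	AcPRX20
AcPRX51	AcPRX4
AcPRX27	AcPRX6
AcPRX62	AcPRX26
AcPRX23	AcPRX1
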