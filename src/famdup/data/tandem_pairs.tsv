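gene_a	gene_b
AcPRX2	AcPRX3
AcPRX2	AcPRX4
AcPRX3	AcPRX4
AcPRX7	AcPRX8
AcPRX10	AcPRX11
AcPRX14	AcPRX15
AcPRX14	AcPRX16
AcPRX18	AcPRX19
AcPRX18	AcPRX20
AcPRX18	AcPRX21
AcPRX19	AcPRX20
AcPRX19	AcPRX21
AcPRX20	AcPRX21
AcPRX40	AcPRX41
AcPRX55	AcPRX56
AcPRX58	AcPRX59
AcPRX68	AcPRX69
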