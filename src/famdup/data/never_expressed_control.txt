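AcPRX5
AcPRX6
AcPRX11
AcPRX15
AcPRX17
AcPRX18
AcPRX19
AcPRX20
AcPRX21
AcPRX31
AcPRX32
AcPRX40
AcPRX49
AcPRX57
AcPRX64
AcPRX65
AcPRX68
AcPRX70
AcPRX71
AcPRX73
AcPRX74
AcPRX76
AcPRX78
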