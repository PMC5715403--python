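HPC	HPC
Cx3Cx2C	Cx3Cx2C
ExRP	ExRP
AGPG	AGPG
TxTxN	TxTxN
Cx2CRxDAxG	Cx2CRxDAxG
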