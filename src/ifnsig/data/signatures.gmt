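ifn	Type I interferon signature (five IFN-I dependent genes upregulated in pustular psoriasis blood)	PLSCR1	OASL	IFI6	IFIT3	IFITM3
il36	IL-36 activity signature (five IL-36 inducible genes robustly expressed in whole blood)	IL1B	PI3	VNN2	TNFAIP6	SERPINB1
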