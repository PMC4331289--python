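# Reference confusion matrix: TESTING phase, winter crops (WIC) panel.
observed	BNS	CKP	OAT	WHT
BNS	8	0	0	0
CKP	0	7	0	1
OAT	0	0	2	3
WHT	0	1	1	27
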