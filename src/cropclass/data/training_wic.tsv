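# Reference confusion matrix: TRAINING evaluation, winter crops (WIC) panel.
observed	BNS	CKP	OAT	WHT
BNS	8	0	0	0
CKP	0	8	0	0
OAT	0	0	5	0
WHT	0	1	0	26
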