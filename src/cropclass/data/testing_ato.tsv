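# Reference confusion matrix: TESTING phase, adult tree orchards (ATO) panel.
observed	CIT	MFO	OLV	POP
CIT	7	0	2	1
MFO	0	8	0	0
OLV	0	1	16	1
POP	1	0	0	7
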