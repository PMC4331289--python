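# Reference confusion matrix: TRAINING evaluation, adult tree orchards
# (ATO) panel. The source prints the citrus row under the token "ORT";
# it is entered here under its crop code CIT.
observed	MFO	OLV	CIT	POP
MFO	8	0	0	0
OLV	0	18	0	0
CIT	0	0	13	0
POP	0	0	0	8
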