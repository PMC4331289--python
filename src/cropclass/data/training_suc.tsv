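# Reference confusion matrix: TRAINING evaluation, summer crops (SUC) panel.
observed	COT	CRN	POT	SUN
COT	11	0	0	0
CRN	0	9	0	0
POT	0	0	5	0
SUN	0	0	0	10
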