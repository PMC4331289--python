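# Reference confusion matrix: TESTING phase, summer crops (SUC) panel.
# The printed SUN row is internally inconsistent in the source (8 correct
# of 10 observed, yet the predicted-total column reads 6); the
# observed-row counts are kept.
observed	COT	CRN	POT	SUN
COT	10	0	0	0
CRN	0	9	0	0
POT	0	0	6	0
SUN	0	0	2	8
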