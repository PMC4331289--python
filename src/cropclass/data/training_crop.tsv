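# Reference confusion matrix: decision-tree TRAINING evaluation over all
# individual crops/land uses; 156 ground-truthed parcels of a published
# multitemporal (7-image) Mediterranean crop-classification study.
# Rows = observed class, columns = predicted class.
observed	BNS	CIT	CIV	CKP	COT	CRN	MFO	OAT	OLV	POP	POT	SUN	WAT	WHT	YTO
BNS	8	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIT	0	6	0	0	0	0	1	0	6	0	0	0	0	0	0
CIV	6	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CKP	0	0	0	8	0	0	0	0	0	0	0	0	0	0	0
COT	0	0	0	0	11	0	0	0	0	0	0	0	0	0	0
CRN	0	0	0	0	1	8	0	0	0	0	0	0	0	0	0
MFO	0	0	0	0	0	0	8	0	0	0	0	0	0	0	0
OAT	5	0	0	0	0	0	0	0	0	0	0	0	0	0	0
OLV	0	0	0	0	0	0	0	0	18	0	0	0	0	0	0
POP	0	0	0	0	0	0	0	0	0	8	0	0	0	0	0
POT	3	0	0	0	0	0	0	0	0	0	2	0	0	0	0
SUN	0	0	0	0	0	0	0	0	0	0	0	10	0	0	0
WAT	0	0	0	0	0	0	0	0	0	0	0	0	7	0	0
WHT	2	2	0	0	0	0	0	0	0	0	1	0	0	22	0
YTO	1	0	0	0	0	0	0	0	1	0	0	1	0	0	10
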