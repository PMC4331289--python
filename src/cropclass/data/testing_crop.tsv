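# Reference confusion matrix: TESTING phase — classification of 156
# unidentified parcels by individual-crop SQL rule models; published
# multitemporal Mediterranean crop-classification study.
# Rows = observed class, columns = predicted class.
# The printed source is internally inconsistent in some off-diagonal
# placements (the OAT and POT rows cannot reconcile all printed predicted
# totals); this file keeps the printed observed-row counts, placing
# OAT -> WAT,WHT and POT -> BNS,WHT per the printed column order. The
# diagonal, row totals and OA are unaffected.
observed	BNS	CIV	CKP	COT	CRN	MFO	OAT	OLV	CIT	POP	POT	SUN	WAT	WHT	YTO
BNS	8	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIV	0	7	0	0	0	0	0	0	0	0	0	0	0	0	0
CKP	0	0	8	0	0	0	0	0	0	0	0	0	0	0	0
COT	0	0	0	10	0	0	0	0	0	0	0	0	0	0	0
CRN	0	0	0	1	8	0	0	0	0	0	0	0	0	0	0
MFO	0	0	0	0	0	8	0	0	0	0	0	0	0	0	0
OAT	0	0	0	0	0	0	0	0	0	0	0	0	2	2	0
OLV	0	0	0	0	0	0	0	16	0	0	0	0	0	0	2
CIT	0	0	0	0	0	1	0	5	6	0	0	0	0	0	0
POP	0	0	0	0	0	0	0	0	0	8	0	0	0	0	0
POT	2	0	0	0	0	0	0	0	0	0	0	0	0	2	0
SUN	2	0	0	0	0	0	0	0	0	0	0	8	0	0	0
WAT	0	0	0	0	0	0	0	0	0	0	0	0	7	0	0
WHT	6	0	2	0	0	0	0	0	1	0	0	0	0	20	0
YTO	2	0	0	0	0	0	0	0	0	0	0	2	0	0	10
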