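# Candidate driver genes: frequency of involvement (percent of tumors with concordant aberrant
# expression; underexpression FC<=0.75 for candidate tumor suppressors, overexpression FC>=1.5 for
# candidate oncogenes) in the 31-sample discovery expression set and the 84-sample independent
# validation set. NI = not informative (no gene-specific probe on the validation platform).
# known=yes marks previously established osteosarcoma driver genes.
Gene	Direction	Known	Freq_discovery	Freq_validation
OXSR1	loss	no	97	89
BSG	loss	no	94	70
NT5E	loss	no	84	93
DOCK5	loss	yes	81	90
PLEKHG7	loss	no	77	0
CMTM8	loss	no	68	65
NETO2	loss	no	61	60
ODZ3	loss	no	61	NI
PTEN	loss	yes	45	NI
ERBB4	loss	no	35	0
CD83	gain	no	74	51
RTN1	gain	no	58	74
GPR177	gain	no	48	43
MYC	gain	yes	45	4
POP4	gain	no	35	18
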