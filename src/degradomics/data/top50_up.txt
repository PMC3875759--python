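# Known members of the top-50 tumor-overexpressed protease list (colorectal
# discovery cohort).  The published table prints only the 21 proteases with
# fold > 4; MMP10, KLK6 and KLK8 are named in the text as additional
# overexpressed members.  The remaining ranks were not published, so this
# list is partial (24/50 known); proportions downstream use the declared
# n = 50 denominator.
DPEP1
TMPRSS3
PRSS22
ABHD7
MMP3
MMP7
KLK10
MMP1
MMP11
ADAMTS12
PRSS33
KLK11
SHH
ADAM12
FAP
OTUB2
CTSL2
MME
QPCT
TMPRSS13
GZMB
MMP10
KLK6
KLK8
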