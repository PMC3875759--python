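# Proteases and protease inhibitors differentially expressed in colorectal
# cancer (discovery cohort, 14 tumor/normal pairs; median RQ magnitudes).
# `fold` is the published fold-change magnitude: median RQ for the up
# section, 1/median RQ for the down section.
#% array_background	266	264
#% expressed_background	219	255
symbol	localization	activity	catalytic_class	transcript_length_bp	direction	fold
DPEP1	EC-TM	protease			up	61.2
TMPRSS3	EC-TM	protease			up	20.0
PRSS22	EC-S	protease			up	18.3
ABHD7	EC-TM	NPH			up	18.0
MMP3	EC-S	protease			up	17.8
MMP7	EC-S	protease			up	16.6
KLK10	EC-S	protease			up	11.5
MMP1	EC-S	protease			up	10.7
MMP11	EC-S	protease			up	9.9
ADAMTS12	EC-S	protease			up	8.9
PRSS33	EC-S	protease			up	8.9
KLK11	EC-S	protease			up	8.3
SHH	EC-TM	protease			up	7.8
ADAM12	EC-TM	protease			up	7.3
FAP	EC-TM	protease			up	7.1
OTUB2	IC	protease			up	5.7
CTSL2	IC	protease			up	5.3
MME	EC-TM	protease			up	5.3
QPCT	EC-S	NPH			up	5.3
TMPRSS13	EC-TM	protease			up	4.8
GZMB	EC-S	protease			up	4.2
CST1	EC-S	inhibitor			up	80.0
SERPINB7	EC-S	inhibitor			up	20.7
SERPINB5	EC-S	inhibitor			up	14.0
ASPA	IC	NPH			down	40.1
CMA1	EC-S	protease			down	21.0
ANPEP	EC-TM	protease			down	13.9
CTSG	EC-S	protease			down	13.2
DPP10	EC-TM	NPH			down	12.1
DPP6	EC-TM	NPH			down	11.6
DPYSL5	IC	NPH			down	9.9
MMP28	EC-S	protease			down	9.2
TPSD1	EC-S	protease			down	9.0
PCSK2	IC	protease			down	8.9
MEP1B	EC-TM	protease			down	8.7
MASP3	EC-S	protease			down	8.7
CAPN9	IC	protease			down	8.7
USP2	IC	protease			down	8.6
AQPEP	EC-TM	protease			down	7.9
ADAMDEC1	EC-S	protease			down	7.9
CFD	EC-S	protease			down	7.3
PAPPA2	EC-S	protease			down	6.8
GZMM	IC	protease			down	6.5
CPM	EC-TM	protease			down	6.4
ADAM33	EC-TM	protease			down	6.3
UCHL1	IC	protease			down	5.9
PCSK5	IC	protease			down	5.9
ELA2	EC-S	protease			down	5.6
TPSAB1	EC-S	protease			down	5.4
MEP1A	EC-TM	protease			down	5.2
ABHD12B	IC	NPH			down	5.1
RELN	EC-S	protease			down	4.9
PHEX	IC	protease			down	4.9
TLL1	EC-S	protease			down	4.9
CPA3	EC-S	protease			down	4.6
NAALADL1	EC-TM	protease			down	4.4
NAALAD2	EC-TM	protease			down	4.4
CAPN13	IC	protease			down	4.1
ADAMTS1	EC-S	protease			down	4.1
SERPINA3	EC-S	inhibitor			down	4.2
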