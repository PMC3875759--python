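# Protease genes reported as somatically mutated in breast cancer that
# intersect the differential lists (published excerpt; user-supplied
# catalogs replace this for new analyses).
TMPRSS3
ADAM12
MMP10
MASP3
ABHD12B
TLL1
CPA3
DPP6
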