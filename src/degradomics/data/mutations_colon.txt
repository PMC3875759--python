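# Protease genes reported as somatically mutated in colon cancer that
# intersect the differential lists (published excerpt; user-supplied
# catalogs replace this for new analyses).
DPEP1
MMP11
DPP10
PCSK2
ADAM33
RELN
CAPN13
ADAMTS1
ADAMTS15
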