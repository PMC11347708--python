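gene	hallmark
ACE	altered intercellular communication
ATM	genomic instability
BLM	genomic instability
BRCA2	genomic instability
CETP	deregulated nutrient sensing
DOCK8	chronic inflammation
FANCA	genomic instability
FANCI	genomic instability
NUDT1	genomic instability
SIRT1	disabled macroautophagy
XRCC5	genomic instability
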