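# Protein-name dictionary (category: proteins -> PROTEIN)
# Best-effort seed list; replace with a UniProtKB-derived dictionary for
# production curation.
tau
ogt
oga
mgea5
p53
tp53
akt
akt1
sp1
nup62
nup153
synapsin
crtc2
foxo1
hcf1
camkiv
casein kinase ii
alphasynuclein
amyloid precursor protein
ezh2
snap29
tab1
irs1
creb
myc
histone h2b
vimentin
keratin
actin
tubulin
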