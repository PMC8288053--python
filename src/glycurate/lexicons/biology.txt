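# General molecular-biology vocabulary (category: biology)
gene
genes
enzyme
enzymes
substrate
substrates
domain
domains
chromatin
transcription
translation
signaling
pathway
pathways
apoptosis
metabolism
mutation
mutations
mutant
nucleus
cytoplasm
stability
degradation
localization
interaction
regulation
expression
proteasome
ubiquitin
isoform
promoter
receptor
mitochondria
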