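# Organism-name dictionary (category: organisms -> ORGANISM)
human
humans
mouse
mice
rat
rats
drosophila
zebrafish
yeast
arabidopsis
homo sapiens
mus musculus
rattus norvegicus
caenorhabditis elegans
drosophila melanogaster
danio rerio
saccharomyces cerevisiae
escherichia coli
xenopus
arabidopsis thaliana
toxoplasma
plasmodium
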