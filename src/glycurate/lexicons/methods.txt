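# Experimental-methods vocabulary (category: methods)
western blot
western blotting
immunoblot
immunoblotting
immunoprecipitation
mass spectrometry
spectrometry
chromatography
electrophoresis
transfection
mutagenesis
pcr
elisa
microscopy
immunofluorescence
click chemistry
wheat germ agglutinin
pulldown
crispr
knockdown
knockout
overexpression
radiolabeling
beta elimination
galactosyltransferase labeling
antibody
antibodies
immunostaining
cotransfection
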