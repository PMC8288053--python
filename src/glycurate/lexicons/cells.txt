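# Cell lines and cell types (category: cells)
hela
hek293
cos7
cho
jurkat
shsy5y
3t3
neuro2a
neuron
neurons
hepatocyte
hepatocytes
lymphocyte
lymphocytes
fibroblast
fibroblasts
myocyte
myocytes
cardiomyocyte
cardiomyocytes
astrocyte
astrocytes
erythrocyte
erythrocytes
macrophage
macrophages
podocyte
podocytes
islet
islets
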