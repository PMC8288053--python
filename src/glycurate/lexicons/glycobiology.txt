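# Glycobiology vocabulary (category: glycobiology)
glycosylation
glycan
glycans
glycoprotein
glycoproteins
glycosyltransferase
glycosyltransferases
glycoside
glycosidase
hexosamine
glucosamine
nacetylglucosamine
acetylglucosamine
udpglcnac
lectin
lectins
sugar
sugars
carbohydrate
carbohydrates
sialic
glycomics
glycoform
glycoforms
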