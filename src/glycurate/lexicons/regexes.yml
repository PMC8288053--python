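# Regex-tagged categories. Patterns are compiled case-insensitively; use a
# scoped (?-i:...) group where letter case is the signal (peptide strings).
# Text reaching the tagger has been cleaned: hyphens and other punctuation
# are already deleted in place, so patterns match the merged variants
# ("O-GlcNAc" arrives as "OGlcNAc").
categories:
  conclusion:
    tag: CONCLUSION
    patterns:
      - '\b(?:demonstrat\w*|conclud\w*|confirm\w*|establish\w*|reveal\w*|show(?:s|ed|n)?|indicat\w*|suggest\w*|evidences?)\b'
  description:
    tag: DESCRIPTION
    patterns:
      - '\b(?:observ\w*|measur\w*|quantif\w*|analy[sz]\w*|perform\w*|incubat\w*|examin\w*)\b'
  peptides:
    tag: PEPTIDES
    patterns:
      - '(?-i:\b[ACDEFGHIKLMNPQRSTVWY]{6,}\b)'
      - '\b(?:glyco)?peptides?\b'
  nucleic acids:
    tag: NUCLEICACIDS
    patterns:
      - '(?-i:\b[acgtu]{8,}\b)'
      - '\b(?:dna|rna|mrna|cdna|sirnas?|oligonucleotides?|plasmids?|nucleotides?)\b'
  pronominial:
    tag: PRONOMINIAL
    patterns:
      - '\b(?:we|our|us|herein|here we)\b'
  ser/thr:
    tag: STSITES
    patterns:
      - '\b(?:ser(?:ine)?|thr(?:eonine)?) ?\d{1,4}\b'
      - '\b[st]\d{1,4}\b'
  amino acids:
    tag: AMINOACIDS
    patterns:
      - '\b(?:alanine|arginine|asparagine|aspartate|cysteine|glutamine|glutamate|glycine|histidine|isoleucine|leucine|lysine|methionine|phenylalanine|proline|serine|threonine|tryptophan|tyrosine|valine)s?\b'
      - '\b(?:ala|arg|asn|asp|cys|gln|glu|gly|his|ile|leu|lys|met|phe|pro|trp|tyr|val) ?\d{1,4}\b'
  phosphorylation:
    tag: PHOSPHO
    patterns:
      - '\b(?:de)?phospho\w*\b'
      - '\b(?:kinases?|phosphatases?)\b'
  o-glcnac:
    tag: OGLCNAC
    patterns:
      - '\bo ?glcnac\w*\b'
      - '\bglcnacylat\w*\b'
      - '\bo ?linked (?:n ?acetylglucosamine|glcnac\w*)\b'
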