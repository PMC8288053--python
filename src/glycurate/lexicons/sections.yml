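# Section-header patterns (matched MULTILINE, case-insensitive) used to
# narrow a document to its results/discussion spans before tagging.
abstract: '^\s*abstract\b.*$'
introduction: '^\s*(?:\d+\.?\s*)?introduction\b.*$'
methods: '^\s*(?:\d+\.?\s*)?(?:materials? and methods|methods|experimental procedures)\b.*$'
results: '^\s*(?:\d+\.?\s*)?results(?: and discussion)?\b.*$'
discussion: '^\s*(?:\d+\.?\s*)?discussion\b.*$'
references: '^\s*(?:references|bibliography|acknowledg\w*)\b.*$'
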