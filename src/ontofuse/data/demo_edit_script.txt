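# demonstration edit script for the packaged fixture ontology
# one operation per line: op<TAB>arg1<TAB>arg2
deselect	allantois
normalize_labels	-/,	cell,cells,human
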