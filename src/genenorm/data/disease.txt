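# disease trigger tokens (case-insensitive)
disorder
disorders
disease
diseases
syndrome
syndromes
cancer
cancers
carcinoma
tumor
tumors
tumour
leukemia
lymphoma
deficiency
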