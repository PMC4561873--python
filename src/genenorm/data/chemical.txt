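# chemical trigger tokens
acid
ring
trivial
methyl
ethyl
phenyl
hydroxy
amine
oxide
chloride
sulfate
phosphate
glucose
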