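# suffix triggers retyping a mention as a protein domain/motif
domain
domains
motif
motifs
finger
fingers
repeat
repeats
box
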