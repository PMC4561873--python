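# domain/region trigger tokens
domain
domains
motif
motifs
region
regions
finger
fingers
repeat
repeats
terminus
terminal
site
sites
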