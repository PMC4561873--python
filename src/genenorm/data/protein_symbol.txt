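# amino-acid names (protein symbol triggers)
alanine
arginine
asparagine
aspartate
cysteine
glutamine
glutamate
glycine
histidine
isoleucine
leucine
lysine
methionine
phenylalanine
proline
serine
threonine
tryptophan
tyrosine
valine
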