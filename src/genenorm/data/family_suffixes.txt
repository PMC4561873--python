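# suffix triggers retyping a mention as a gene family
family
families
subfamily
superfamily
proteins
-related proteins
related proteins
homologs
isoforms
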