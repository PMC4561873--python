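# gene-context trigger tokens
gene
genes
protein
proteins
strains
strain
expression
expressed
receptor
receptors
kinase
kinases
transcription
promoter
mutation
mutations
allele
alleles
homolog
ortholog
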