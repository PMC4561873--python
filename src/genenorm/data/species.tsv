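9606	human
9606	humans
9606	Homo sapiens
9606	patient
9606	patients
10090	mouse
10090	mice
10090	murine
10090	Mus musculus
10116	rat
10116	rats
10116	Rattus norvegicus
7227	fly
7227	flies
7227	Drosophila
7227	Drosophila melanogaster
4932	yeast
4932	Saccharomyces cerevisiae
7955	zebrafish
7955	Danio rerio
562	Escherichia coli
562	E. coli
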