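# genenorm

Gene mention recognition and gene normalization for biomedical abstracts.

Automatically reading the genetics literature starts with two tasks: the
**gene mention (GM)** task — finding the character offsets of gene names
in text — and the **gene normalization (GN)** task — returning the
database concept identifiers (e.g. Entrez Gene ids) for the genes a
document discusses. Both are hard for the same reasons: authors write the
same gene many ways ("ESR1" / "ESR-1" / "estrogen receptor alpha (ERα)" /
"BRCA1/2"), and the same name can mean different genes ("TEL1" is both
*ATM* and *ETV6*) or the same gene in different species (*erbb2*, human
or mouse). `genenorm` is an end-to-end, trainable pipeline for both
tasks, aimed at text-mining researchers and biocurators who need typed
gene spans plus per-document identifier sets from PubMed-style abstracts.

The design treats gene **families** and protein **domains** as
first-class entity types rather than noise: a tagger that knows "OSBP-related
proteins" is a family name stops emitting false gene identifiers for it,
and a detected "PNT domain" mention is exactly the evidence that resolves
"TEL1" to *ETS translocation factor variant 6* instead of *ATM*.

## Method

**Mention recognition.** Abstracts are tokenized at punctuation,
letter/digit boundaries and case transitions ("hTIF1" → "h"+"TIF"+"1");
each token is encoded by five feature families (linguistic, character
counts, semantic lexicon flags, case patterns, ±3-token context) and
labeled with the BIEO scheme (B/I/E × {Gene, FamilyName, DomainMotif}
plus O) by an order-2 linear-chain conditional random field trained with
L-BFGS on the L2-regularized conditional log-likelihood. Four
postprocessing rules arbitrate the types document-wide: suffix triggers,
prefix relations (TIF1 / TIF1alpha), abbreviation long-form→short-form
propagation, and a per-document majority vote.

**Normalization.** Gene-typed mentions (after composite expansion —
"BRCA1/2" → BRCA1, BRCA2) are matched against a lexicon by exact
normalized lookup, falling back to a bag-of-words cosine over
inverse-name-frequency weights w(t) = ln(1 + N/df(t)). Candidates are
re-ranked with family/domain context bonuses, filtered softly by the
species assigned to each mention (prefix cues, nearby species tags,
document majority, default human), and short forms inherit their long
form's identifier. Families and domains contribute context only — never
identifiers.

Everything is testable offline: `genenorm.synthetic` generates seeded
lexicons and fully annotated corpora (mention spans, types, taxids,
abbreviations, composites, document id sets) with the class mixture of
curated gene corpora.

## Worked example

`examples/04_end_to_end.py` trains on 40 synthetic documents and
annotates 10 held-out ones:

```
mention-level strict  P=1.000 R=0.967 F1=0.983
document-level ids    P=1.000 R=1.000 F1=1.000

first held-out document: 10000000
    14-19   Gene         'VLRF1' ids=['137']
    42-47   Gene         'VLRF1' ids=['137']
   108-119  DomainMotif  'WD40 domain' ids=[]
   139-144  Gene         'VLRF1' ids=['137']
document identifier set: ['137']
```

The first two lines are micro-averaged precision / recall / F-measure:
strict mention scoring requires exact (start, end, type) agreement with
gold; document-level scoring compares predicted and gold identifier sets
per document. The listing shows the typed spans with their resolved
identifiers — the domain mention correctly yields no identifier but
remains available as disambiguation context. The other example scripts
walk through tokenization and features (`01`), the typing rules,
abbreviation and composite machinery (`02`), and lexicon matching with
domain-assisted disambiguation (`03`).

A thin CLI wraps the same library: `genenorm synth` (generate fixtures),
`genenorm train`, `genenorm tag` (annotate a PubTator file, PubTator or
BioC XML out), and `genenorm eval` (mention- or document-level scoring
of predicted vs gold PubTator files).

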