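"""Normalizing gene mentions to concept identifiers.

Exact match works on aggressively normalized names (case, hyphens, Greek
letters); bag-of-words match scores weighted token overlap; and family or
domain mentions elsewhere in the document break ties between genes that
share a name.
"""

from genenorm import Candidate, disambiguate, exact_match
from genenorm.normalizer import LexiconEntry, bow_score, build_index

entries = [
    LexiconEntry("472", "9606", ("TEL1", "ATM serine/threonine kinase")),
    LexiconEntry("2120", "9606",
                 ("TEL1", "ETS translocation factor variant 6"),
                 family_terms=("ETS translocation factor",),
                 domain_terms=("PNT",)),
    LexiconEntry("9", "9606", ("GHF-1 transcription factor",)),
]
index = build_index(entries)

print(exact_match("ESR1", index))       # [] — not in this lexicon
print(exact_match("TEL1", index))       # ['472', '2120'] — ambiguous!

# orthographic and morphological variants still score highly
print(round(bow_score("GHF-1 transcriptional factor",
                      entries[2], index), 3))   # 1.0 after stemming

# the document mentions a "PNT domain"; only gene 2120 carries that
# domain, so the ambiguity resolves
cands = [Candidate(g, 1.0, "exact", "9606")
         for g in exact_match("TEL1", index)]
ranked = disambiguate(cands, index, domain_context=["PNT domain"])
print([(c.gene_id, round(c.score, 2)) for c in ranked])
# [('2120', 1.3), ('472', 1.0)] — the domain-consistent gene wins.
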