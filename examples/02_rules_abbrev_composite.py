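"""Type arbitration rules, abbreviation pairs and composite mentions.

After the statistical tagger proposes spans, deterministic document-level
rules fix up entity types, and composite spans are expanded into their
constituent gene names before normalization.
"""

from genenorm import (expand, find_pairs, majority_rule, prefix_rule,
                      suffix_rule)
from genenorm.types import Mention, MentionType

# suffix rule: the trailing trigger word decides family vs domain
m = Mention(0, 21, "OSBP-related proteins", MentionType.GENE)
print(suffix_rule(m).type)            # FamilyName
m = Mention(0, 11, "LIM1 domain", MentionType.GENE)
print(suffix_rule(m).type)            # DomainMotif

# prefix rule: "TIF1" next to "TIF1alpha" names the family, not a gene
tif1 = Mention(0, 4, "TIF1", MentionType.GENE)
tif1a = Mention(10, 19, "TIF1alpha", MentionType.GENE)
prefix_rule([tif1, tif1a])
print(tif1.type)                      # FamilyName

# majority rule: 2 gene + 3 family votes -> all five become family
mentions = [Mention(i * 10, i * 10 + 4, "hif1",
                    MentionType.GENE if i < 2 else MentionType.FAMILY)
            for i in range(5)]
majority_rule(mentions)
print({m.type for m in mentions})     # {FamilyName}

# abbreviation detection by right-to-left parenthetical alignment
for p in find_pairs("estrogen receptor alpha (ERα) binds DNA."):
    print(p.short_text, "<->", p.long_text)

# composite mentions denote several concepts at once
print(expand("BRCA1/2"))              # ['BRCA1', 'BRCA2']
print(expand("SMADs 1, 5, and 8"))    # ['SMAD1', 'SMAD5', 'SMAD8']
print(expand("ERK1-3"))               # ['ERK1', 'ERK2', 'ERK3']
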