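"""Tokenization and the feature families fed to the sequence tagger.

Gene names mix cases, digits and punctuation ("hTIF1", "ESR-1"), so the
tokenizer splits at every character-class boundary and the feature
extractor summarizes each piece by shape, counts and lexicon membership.
"""

from genenorm import tokenize, split_sentences
from genenorm.features import (SemanticLexiconSet, case_patterns,
                               char_counts, extract_features)

for word in ("hTIF1", "ESR-1", "ERα"):
    print(word, "->", [t.text for t in tokenize(word)])
# hTIF1 splits into "h" / "TIF" / "1": one token per case/digit run.

text = "The hTIF1 protein is studied. It causes a disorder."
print("sentences:", len(split_sentences(text)))

print("case patterns of BRCA1:", case_patterns("BRCA1"))
# ('AAAA0', 'A0', 'a0', 'a'): char-by-char shape, collapsed, case-folded,
# and a single summary symbol.
print("char counts of hTIF1:", char_counts("hTIF1"))

toks = tokenize("a disorder")
feats = extract_features(toks, SemanticLexiconSet.default())
print("is 'disorder' a disease trigger?", feats[1]["lex_disease"])
# True: semantic trigger lists let the tagger separate genes from other
# biomedical concepts.
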