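"""Train the full pipeline on a small synthetic corpus and annotate
held-out documents.

Runs in about half a minute: generates a 60-gene lexicon and 40 annotated
training documents, fits the order-2 CRF tagger, then tags and normalizes
10 unseen documents and prints mention- and identifier-level scores.
"""

import warnings

from genenorm import docid_prf, mention_prf
from genenorm.normalizer import build_index
from genenorm.pipeline import strip_annotations, train_pipeline
from genenorm.synthetic import generate_corpus, generate_lexicon

entries, species_lex = generate_lexicon(60, n_species=3, seed=7)
index = build_index(entries)
train_docs = generate_corpus(entries, species_lex, 40, seed=11)
test_docs = generate_corpus(entries, species_lex, 10, seed=12)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    pipe = train_pipeline(train_docs, index, species_lex)

pred = [strip_annotations(d) for d in test_docs]
pipe.annotate_all(pred)

m = mention_prf(test_docs, pred, mode="strict")
d = docid_prf(test_docs, pred)
print(f"mention-level strict  P={m.precision:.3f} R={m.recall:.3f} "
      f"F1={m.f1:.3f}")
print(f"document-level ids    P={d.precision:.3f} R={d.recall:.3f} "
      f"F1={d.f1:.3f}")
# F1 near 1.0 on this clean synthetic text: spans, types and identifiers
# are recovered almost perfectly when names come from the known lexicon.

doc = pred[0]
print("\nfirst held-out document:", doc.doc_id)
for mention in doc.mentions:
    print(f"  {mention.start:>4}-{mention.end:<4} {mention.type.value:<12}"
          f" {mention.text!r} ids={mention.ids}")
print("document identifier set:", sorted(doc.doc_ids))
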