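"""End-to-end annotation: mention recognition followed by normalization.

The two-step architecture — first a sequence tagger finds gene / family /
domain spans and typing rules arbitrate their classes, then species
assignment and lexicon matching attach concept identifiers to the gene
spans — is wrapped here so callers can go from a bare document to a fully
annotated one in a single call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import abbrev, species, tagger, typing_rules
from .features import SemanticLexiconSet
from .normalizer import (LexiconIndex, NormalizationResult, NormalizerConfig,
                         normalize_document)
from .tokenizer import split_sentences
from .types import Document, MentionType


@dataclass
class Pipeline:
    """A trained tagger plus the lexicons needed for normalization."""

    model: tagger.TaggerModel
    index: LexiconIndex
    species_lexicon: dict[str, str]
    lexicons: SemanticLexiconSet = None
    normalizer_config: NormalizerConfig = field(
        default_factory=NormalizerConfig)

    def __post_init__(self):
        if self.lexicons is None:
            self.lexicons = SemanticLexiconSet.default(
                gene_vocab=self.index.all_names())

    def annotate(self, doc: Document) -> NormalizationResult:
        """Fill ``doc`` with mentions, species tags, abbreviation pairs and
        identifiers; returns the normalization detail."""
        text = doc.text
        doc.abbrev_pairs = abbrev.find_pairs(text)
        doc.mentions = tagger.tag_document(self.model, doc, self.lexicons)
        typing_rules.apply_typing_rules(doc.mentions, doc.abbrev_pairs)
        doc.species_tags = species.tag_species(text, self.species_lexicon)
        gene_mentions = [m for m in doc.mentions
                         if m.type == MentionType.GENE]
        species.assign_species(
            gene_mentions, doc.species_tags, text,
            gene_names=self.index.all_names(),
            default_taxid=self.normalizer_config.default_taxid,
            sentences=split_sentences(text),
        )
        return normalize_document(doc, self.index, self.normalizer_config)

    def annotate_all(self, docs: list[Document]) -> list[NormalizationResult]:
        return [self.annotate(d) for d in docs]


def train_pipeline(corpus: list[Document], index: LexiconIndex,
                   species_lexicon: dict[str, str],
                   tagger_config: tagger.TaggerConfig | None = None,
                   normalizer_config: NormalizerConfig | None = None
                   ) -> Pipeline:
    """Train the tagger on an annotated corpus and assemble a pipeline."""
    lexicons = SemanticLexiconSet.default(gene_vocab=index.all_names())
    for doc in corpus:
        if not doc.abbrev_pairs:
            doc.abbrev_pairs = abbrev.find_pairs(doc.text)
    model = tagger.train(corpus, lexicons, tagger_config)
    return Pipeline(model=model, index=index,
                    species_lexicon=species_lexicon, lexicons=lexicons,
                    normalizer_config=normalizer_config
                    or NormalizerConfig())


def strip_annotations(doc: Document) -> Document:
    """A copy of ``doc`` with only id and text, for held-out evaluation."""
    return Document(doc_id=doc.doc_id, title=doc.title,
                    abstract=doc.abstract)
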