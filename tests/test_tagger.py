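"""Tagger: label repair, mention assembly, training contract."""

import warnings

import pytest
from hypothesis import given, settings, strategies as st

from genenorm.evaluation import mention_prf
from genenorm.features import SemanticLexiconSet
from genenorm.pipeline import strip_annotations, train_pipeline
from genenorm.tagger import (LABELS, labels_to_mentions, repair_labels,
                             tag_document, train)
from genenorm.tokenizer import tokenize
from genenorm.types import Document, MentionType


@pytest.mark.parametrize(
    ("raw", "repaired"),
    [
        (["I-Gene", "E-Gene"], ["B-Gene", "E-Gene"]),
        (["O", "O"], ["O", "O"]),
        (["B-Gene", "I-FamilyName", "E-Gene"],
         ["B-Gene", "I-Gene", "E-Gene"]),
        (["O", "E-DomainMotif"], ["O", "B-DomainMotif"]),
        (["B-Gene", "E-FamilyName"], ["B-Gene", "E-Gene"]),
        ([], []),
    ],
)
def test_repair_examples(raw, repaired):
    assert repair_labels(raw) == repaired


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.sampled_from(LABELS), max_size=12))
def test_repair_idempotent_and_assemblable(labels):
    from genenorm.types import Token

    once = repair_labels(labels)
    assert repair_labels(once) == once
    words = []
    text = ""
    for i in range(len(labels)):
        if text:
            text += " "
        w = f"tok{i}"
        words.append(Token(w, len(text), len(text) + len(w)))
        text += w
    mentions = labels_to_mentions(once, words, text)
    for a, b in zip(mentions, mentions[1:]):
        assert a.end <= b.start  # non-overlapping, ordered
    for m in mentions:
        assert text[m.start:m.end] == m.text


def test_labels_to_mentions_examples():
    text = "BRCA1"
    toks = tokenize(text)  # BRCA / 1
    mentions = labels_to_mentions(["B-Gene", "E-Gene"], toks, text)
    assert len(mentions) == 1
    assert (mentions[0].text, mentions[0].type) == ("BRCA1",
                                                    MentionType.GENE)
    assert labels_to_mentions(["O", "O"], toks, text) == []
    text2 = "TP53 and ESR1"
    toks2 = tokenize(text2)  # TP 53 and ESR 1
    labels2 = ["B-Gene", "E-Gene", "O", "B-Gene", "E-Gene"]
    out = labels_to_mentions(labels2, toks2, text2)
    assert [m.text for m in out] == ["TP53", "ESR1"]


def test_train_rejects_empty_and_unlabeled():
    with pytest.raises(ValueError):
        train([])
    doc = Document(doc_id="1", title="Nothing here.", abstract="None.")
    with pytest.raises(ValueError):
        train([doc])


def test_training_set_recall(trained_pipeline, small_corpus):
    pred = [strip_annotations(d) for d in small_corpus]
    trained_pipeline.annotate_all(pred)
    prf = mention_prf(small_corpus, pred, mode="strict")
    assert prf.f1 >= 0.95


def test_retraining_is_deterministic(small_lexicon, small_index,
                                     small_corpus, heldout_corpus,
                                     trained_pipeline):
    _, species_lex = small_lexicon
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        again = train_pipeline(small_corpus, small_index, species_lex)
    lexicons = trained_pipeline.lexicons
    for doc in heldout_corpus[:5]:
        bare = strip_annotations(doc)
        a = tag_document(trained_pipeline.model, bare, lexicons)
        b = tag_document(again.model, bare, lexicons)
        assert [(m.start, m.end, m.type) for m in a] == \
               [(m.start, m.end, m.type) for m in b]


def test_model_save_load_round_trip(tmp_path, trained_pipeline,
                                    heldout_corpus):
    from genenorm.tagger import TaggerModel
    path = tmp_path / "model.npz"
    trained_pipeline.model.save(path)
    loaded = TaggerModel.load(path)
    lexicons = trained_pipeline.lexicons
    for doc in heldout_corpus[:3]:
        bare = strip_annotations(doc)
        a = tag_document(trained_pipeline.model, bare, lexicons)
        b = tag_document(loaded, bare, lexicons)
        assert [(m.start, m.end, m.type) for m in a] == \
               [(m.start, m.end, m.type) for m in b]


def test_template_mismatch_rejected(trained_pipeline):
    from genenorm.tagger import decode
    with pytest.raises(ValueError):
        decode(trained_pipeline.model, [], template_version="other")


def test_stopword_sentence_decodes_to_no_mentions(trained_pipeline):
    doc = Document(
        doc_id="x",
        title="Further studies will be needed to confirm this observation.",
        abstract="These results suggest a new regulatory mechanism.",
    )
    lex = trained_pipeline.lexicons
    assert tag_document(trained_pipeline.model, doc, lex) == []


def test_injected_gene_sentence_is_found(trained_pipeline, heldout_corpus):
    doc = heldout_corpus[0]
    bare = strip_annotations(doc)
    found = tag_document(trained_pipeline.model, bare,
                         trained_pipeline.lexicons)
    gold_gene_spans = {(m.start, m.end) for m in doc.mentions
                       if m.type == MentionType.GENE}
    pred_spans = {(m.start, m.end) for m in found}
    assert gold_gene_spans & pred_spans
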