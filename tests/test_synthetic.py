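"""Synthetic lexicon / corpus generator contracts."""

import pytest

from genenorm.normalizer import build_index, exact_match
from genenorm.synthetic import (CorpusParams, generate_corpus,
                                generate_lexicon)
from genenorm.types import MentionType


def test_minimal_lexicon():
    entries, species = generate_lexicon(1, 1, seed=0)
    assert len(entries) == 1
    assert entries[0].names
    assert species


def test_bad_counts_rejected():
    with pytest.raises(ValueError):
        generate_lexicon(0)
    with pytest.raises(ValueError):
        generate_lexicon(5, n_species=0)


def test_same_seed_same_output():
    a, _ = generate_lexicon(40, 3, seed=9)
    b, _ = generate_lexicon(40, 3, seed=9)
    assert a == b
    entries, slex = generate_lexicon(20, 2, seed=9)
    d1 = generate_corpus(entries, slex, 5, seed=10)
    d2 = generate_corpus(entries, slex, 5, seed=10)
    assert [(d.doc_id, d.text) for d in d1] == \
           [(d.doc_id, d.text) for d in d2]
    assert [d.mentions for d in d1] == [d.mentions for d in d2]


def test_ambiguity_injection():
    entries, _ = generate_lexicon(100, 3, seed=1, ambiguity_fraction=0.2)
    by_name = {}
    for e in entries:
        for n in e.names:
            by_name.setdefault(n, set()).add(e.gene_id)
    assert any(len(ids) > 1 for ids in by_name.values())
    # but (name, taxid) stays unique so gold ids remain recoverable
    by_name_tax = {}
    for e in entries:
        for n in e.names:
            by_name_tax.setdefault((n, e.taxid), set()).add(e.gene_id)
    assert all(len(ids) == 1 for ids in by_name_tax.values())


def test_zero_docs():
    entries, slex = generate_lexicon(5, 2, seed=2)
    assert generate_corpus(entries, slex, 0, seed=3) == []


def test_mention_text_matches_slice_everywhere():
    entries, slex = generate_lexicon(40, 3, seed=4)
    for doc in generate_corpus(entries, slex, 25, seed=5):
        text = doc.text
        for m in doc.mentions:
            assert text[m.start:m.end] == m.text
        for t in doc.species_tags:
            assert text[t.start:t.end] == t.name


def test_composites_present_in_gold():
    entries, slex = generate_lexicon(60, 3, seed=6)
    docs = generate_corpus(entries, slex, 100, seed=7)
    assert any(len(m.ids) > 1 for d in docs for m in d.mentions)


def test_mention_class_mixture_is_gene_heavy():
    entries, slex = generate_lexicon(60, 3, seed=8)
    docs = generate_corpus(entries, slex, 150, seed=9)
    counts = {t: 0 for t in MentionType}
    for d in docs:
        for m in d.mentions:
            counts[m.type] += 1
    total = sum(counts.values())
    assert counts[MentionType.GENE] / total > 0.55
    assert counts[MentionType.FAMILY] > counts[MentionType.DOMAIN] > 0


def test_gold_ids_recoverable_by_lexicon_oracle():
    from genenorm import composite

    entries, slex = generate_lexicon(60, 3, seed=10, ambiguity_fraction=0.2)
    idx = build_index(entries)
    docs = generate_corpus(entries, slex, 40, seed=11)
    for doc in docs:
        recovered = set()
        for m in doc.mentions:
            if m.type != MentionType.GENE:
                continue
            for constituent in composite.expand(m.text):
                ids = exact_match(constituent, idx, taxid=m.taxid)
                assert len(ids) == 1
                recovered.add(ids[0])
        assert recovered == doc.doc_ids


def test_custom_params_respected():
    entries, slex = generate_lexicon(30, 2, seed=12)
    params = CorpusParams(sentences_range=(2, 2), genes_per_doc=(1, 1))
    docs = generate_corpus(entries, slex, 10, seed=13, params=params)
    for d in docs:
        # two sentences after the title
        assert len(d.abstract.split(". ")) <= 3
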