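"""Normalization: exact match, bag-of-words scoring, disambiguation."""

import math

import numpy as np
import pytest

from genenorm.normalizer import (Candidate, LexiconEntry, NormalizerConfig,
                                 bow_candidates, bow_score, build_index,
                                 disambiguate, exact_match, name_tokens,
                                 normalize_document, read_gene_lexicon,
                                 write_gene_lexicon)
from genenorm.synthetic import generate_lexicon
from genenorm.types import Document, Mention, MentionType


def _entry(gid, *names, taxid="9606", family=(), domain=()):
    return LexiconEntry(gene_id=gid, taxid=taxid, names=tuple(names),
                        family_terms=tuple(family),
                        domain_terms=tuple(domain))


def test_build_index_exact_map():
    idx = build_index([_entry("1", "ABC1")])
    assert set(idx.exact) == {"abc1"}
    idx2 = build_index([_entry("A", "ESR1"), _entry("B", "ESR-1")])
    assert idx2.exact["esr1"] == ["A", "B"]


def test_token_in_all_entries_has_weight_ln2():
    idx = build_index([_entry("1", "kinase alpha"),
                       _entry("2", "kinase beta")])
    assert idx.weight(name_tokens("kinase")[0]) == pytest.approx(math.log(2))


def test_duplicate_gene_id_rejected():
    with pytest.raises(ValueError):
        build_index([_entry("1", "A"), _entry("1", "B")])


def test_exact_match_cases():
    idx = build_index([_entry("10", "ESR1"), _entry("11", "ERα")])
    assert exact_match("ESR1", idx) == ["10"]
    assert exact_match("esr-1", idx) == ["10"]
    assert exact_match("ER alpha", idx) == ["11"]
    assert exact_match("unknown thing", idx) == []


def test_exact_match_taxid_soft_filter():
    idx = build_index([_entry("20", "ERBB2", taxid="9606"),
                       _entry("21", "ERBB2", taxid="10090")])
    assert exact_match("ERBB2", idx, taxid="10090") == ["21"]
    assert exact_match("ERBB2", idx, taxid="9606") == ["20"]
    # filter would empty the list -> homologs retained
    assert exact_match("ERBB2", idx, taxid="7227") == ["20", "21"]


def test_bow_score_bounds_and_examples():
    e = _entry("9", "GHF-1 transcription factor")
    idx = build_index([e])
    assert bow_score("GHF-1 transcription factor", e, idx) == pytest.approx(1.0)
    assert bow_score("completely unrelated words", e, idx) == 0.0
    score = bow_score("GHF-1 transcriptional factor", e, idx)
    assert score > 0.5
    assert score == pytest.approx(1.0)  # stemming merges the variants


def test_bow_score_monotone_in_shared_tokens():
    e = _entry("5", "alpha beta gamma delta")
    idx = build_index([e, _entry("6", "zeta eta theta iota")])
    s1 = bow_score("alpha zeta eta iota", e, idx)
    s2 = bow_score("alpha beta zeta iota", e, idx)  # one more shared token
    assert 0.0 <= s1 <= s2 <= 1.0


def test_bow_candidates_match_brute_force_oracle():
    from tests_oracles import brute_force_bow_rank as brute_force_rank

    entries, _ = generate_lexicon(50, 3, seed=21)
    idx = build_index(entries)
    rng = np.random.default_rng(22)
    all_names = sorted({n for e in entries for n in e.names})
    words = sorted({w for n in all_names for w in n.split()})
    for _ in range(100):
        kind = rng.random()
        if kind < 0.4:
            mention = all_names[int(rng.integers(0, len(all_names)))]
        elif kind < 0.8:  # perturbed name: drop or swap one word
            name = all_names[int(rng.integers(0, len(all_names)))].split()
            if len(name) > 1:
                name.pop(int(rng.integers(0, len(name))))
            mention = " ".join(name) or "x"
        else:  # random word salad
            mention = " ".join(
                words[int(rng.integers(0, len(words)))] for _ in range(3))
        got = [(c.gene_id, c.score)
               for c in bow_candidates(mention, idx, threshold=0.3)]
        want = brute_force_rank(mention, entries, 0.3)
        assert [g for g, _ in got] == [g for g, _ in want]
        for (_, a), (_, b) in zip(got, want):
            assert a == pytest.approx(b)


def test_disambiguate_domain_context_tel1():
    entries = [
        _entry("472", "TEL1", "ATM serine/threonine kinase"),
        _entry("2120", "TEL1", "ETS translocation factor variant 6",
               family=("ETS translocation factor",), domain=("PNT",)),
    ]
    idx = build_index(entries)
    cands = [Candidate(g, 1.0, "exact", "9606")
             for g in exact_match("TEL1", idx)]
    ranked = disambiguate(cands, idx, domain_context=["PNT domain"])
    assert ranked[0].gene_id == "2120"
    # without context the smaller id wins the tie
    ranked_plain = disambiguate(cands, idx)
    assert ranked_plain[0].gene_id == "472"
    # single candidate unchanged
    assert disambiguate([cands[0]], idx)[0].gene_id == "472"


def _doc(text, mentions):
    title, _, abstract = text.partition("\n")
    return Document(doc_id="d1", title=title, abstract=abstract,
                    mentions=mentions)


def test_normalize_document_basic_and_family_excluded():
    idx = build_index([_entry("100", "ABCD1", "alpha binding protein 1")])
    doc = _doc("ABCD1 studies.\nNothing else.",
               [Mention(0, 5, "ABCD1", MentionType.GENE)])
    res = normalize_document(doc, idx)
    assert res.doc_ids == {"100"}

    fam = _doc("ABCD family studies.\nNothing else.",
               [Mention(0, 12, "ABCD family", MentionType.FAMILY)])
    assert normalize_document(fam, idx).doc_ids == set()


def test_normalize_document_composite():
    idx = build_index([_entry("1", "BRCA1"), _entry("2", "BRCA2")])
    doc = _doc("BRCA1/2 are studied.\nMore text.",
               [Mention(0, 7, "BRCA1/2", MentionType.GENE)])
    res = normalize_document(doc, idx)
    assert res.doc_ids == {"1", "2"}
    assert doc.mentions[0].ids == ["1", "2"]


def test_normalize_document_abbrev_override():
    # the short form alone is ambiguous; the long form pins it down
    from genenorm.abbrev import find_pairs
    idx = build_index([
        _entry("300", "TIF1", "transcription initiation factor 1"),
        _entry("301", "TIF1"),
    ])
    text = "transcription initiation factor 1 (TIF1) acts.\nTIF1 binds."
    title, _, abstract = text.partition("\n")
    doc = Document(
        doc_id="d", title=title, abstract=abstract,
        mentions=[
            Mention(0, 33, "transcription initiation factor 1",
                    MentionType.GENE),
            Mention(35, 39, "TIF1", MentionType.GENE),
            Mention(47, 51, "TIF1", MentionType.GENE),
        ],
        abbrev_pairs=find_pairs(text),
    )
    res = normalize_document(doc, idx)
    assert res.doc_ids == {"300"}
    assert all(m.ids == ["300"] for m in doc.mentions)


def test_exact_identity_over_fixture_lexicon(small_lexicon):
    entries, _ = small_lexicon
    idx = build_index(entries)
    for e in entries:
        for name in e.names:
            ids = exact_match(name, idx, taxid=e.taxid)
            assert e.gene_id in ids


def test_lexicon_tsv_round_trip(tmp_path, small_lexicon):
    entries, _ = small_lexicon
    path = tmp_path / "genes.tsv"
    write_gene_lexicon(entries, path)
    back = read_gene_lexicon(path)
    assert back == entries
    bad = tmp_path / "bad.tsv"
    bad.write_text("wrong\theader\n")
    with pytest.raises(ValueError):
        read_gene_lexicon(bad)
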