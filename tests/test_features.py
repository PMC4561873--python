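"""Feature families: case patterns, character counts, affixes, context."""

import pytest

from genenorm.features import (SemanticLexiconSet, affixes, case_patterns,
                               char_counts, encode_features,
                               extract_features)
from genenorm.lingua import porter_stem
from genenorm.tokenizer import tokenize


@pytest.mark.parametrize(
    ("token", "p1", "p2", "p3", "p4"),
    [
        ("BRCA1", "AAAA0", "A0", "a0", "a"),
        ("a", "a", "a", "a", "a"),
        ("Abc123", "Aaa000", "Aa0", "a0", "a"),
        ("hTIF1", "aAAA0", "aA0", "a0", "a"),
        ("123", "000", "0", "0", "0"),
        ("-", "-", "-", "-", "-"),
    ],
)
def test_case_patterns(token, p1, p2, p3, p4):
    assert case_patterns(token) == (p1, p2, p3, p4)


def test_case_patterns_rejects_empty():
    with pytest.raises(ValueError):
        case_patterns("")


@pytest.mark.parametrize(
    ("token", "expected"),
    [
        ("hTIF1", {"upper": 3, "lower": 1, "letters": 4, "digits": 1,
                   "specials": 0}),
        ("", {"upper": 0, "lower": 0, "letters": 0, "digits": 0,
              "specials": 0}),
        ("->", {"upper": 0, "lower": 0, "letters": 0, "digits": 0,
                "specials": 2}),
        ("p_2;", {"upper": 0, "lower": 1, "letters": 1, "digits": 1,
                  "specials": 2}),
    ],
)
def test_char_counts(token, expected):
    assert char_counts(token) == expected


def test_affixes():
    out = affixes("genes")
    assert {out[f"pfx{i}"] for i in range(1, 6)} == {
        "g", "ge", "gen", "gene", "genes"}
    assert affixes("a") == {"pfx1": "a", "sfx1": "a"}
    assert affixes("kinases")["sfx5"] == "nases"


def test_stemmer_merges_morphological_variants():
    assert porter_stem("transcriptional") == porter_stem("transcription")
    assert porter_stem("genes") == "gene"
    assert porter_stem("binding") == "bind"


def test_single_token_sentence_has_no_context_features():
    toks = tokenize("BRCA")
    feats = extract_features(toks)
    assert not any("@" in k for k in feats[0])


def test_disease_lexicon_flag():
    toks = tokenize("disorder")
    feats = extract_features(toks, SemanticLexiconSet.default())
    assert feats[0]["lex_disease"] is True
    assert feats[0]["lex_chem"] is False


def test_window_clipping_at_sentence_start():
    toks = tokenize("alpha beta gamma delta epsilon zeta eta")
    assert len(toks) == 7
    feats = extract_features(toks)
    offsets = {k.split("@")[1] for k in feats[0] if "@" in k}
    assert offsets == {"+1", "+2", "+3"}
    mid = {k.split("@")[1] for k in feats[3] if "@" in k}
    assert mid == {"-3", "-2", "-1", "+1", "+2", "+3"}


def test_window_symmetry():
    toks = tokenize("the BRCA1 gene binds the TP53 protein")
    feats = extract_features(toks)
    for i in range(len(toks)):
        for k in (-3, -2, -1, 1, 2, 3):
            j = i + k
            if 0 <= j < len(toks):
                assert feats[i][f"w@{k:+d}"] == feats[j]["w"]
                assert feats[i][f"stem@{k:+d}"] == feats[j]["stem"]


def test_feature_determinism_and_sorted_encoding():
    toks = tokenize("hTIF1 binds ERα in disorder models")
    a = [encode_features(f) for f in extract_features(toks)]
    b = [encode_features(f) for f in extract_features(toks)]
    assert a == b
    for row in a:
        assert row == sorted(row)


def test_gene_vocab_longest_match():
    lex = SemanticLexiconSet.default(
        gene_vocab=["esr-1", "tp53", "growth factor 1"])
    toks = tokenize("ESR-1 and growth factor 1 bind TP53 today")
    feats = extract_features(toks, lex)
    flagged = [f["w"] for f in feats if f["lex_gene"]]
    assert flagged == ["ESR", "-", "1", "growth", "factor", "1", "TP", "53"]
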