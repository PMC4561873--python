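"""Type arbitration rules: suffix, prefix, abbreviation, majority."""

import copy

import pytest

from genenorm.typing_rules import (abbrev_type_rule, apply_typing_rules,
                                   majority_rule, prefix_rule, suffix_rule)
from genenorm.types import AbbrPair, Mention, MentionType


def _m(text, typ=MentionType.GENE, start=0):
    return Mention(start=start, end=start + len(text), text=text, type=typ)


@pytest.mark.parametrize(
    ("text", "expected"),
    [
        ("OSBP-related proteins", MentionType.FAMILY),
        ("LIM1 domain", MentionType.DOMAIN),
        ("BRCA1", MentionType.GENE),
        ("TIF1 family", MentionType.FAMILY),
        ("zinc finger", MentionType.DOMAIN),
    ],
)
def test_suffix_rule(text, expected):
    assert suffix_rule(_m(text)).type == expected


def test_prefix_rule_retypes_strict_prefixes():
    tif1, tif1a = _m("TIF1"), _m("TIF1alpha", start=20)
    prefix_rule([tif1, tif1a])
    assert tif1.type == MentionType.FAMILY
    assert tif1a.type == MentionType.GENE


def test_prefix_rule_leaves_singletons_and_duplicates():
    solo = _m("BRCA1")
    prefix_rule([solo])
    assert solo.type == MentionType.GENE
    a, b = _m("p53"), _m("p53", start=10)
    prefix_rule([a, b])
    assert a.type == b.type == MentionType.GENE


def test_prefix_rule_ignores_composite_superstrings():
    brca1, comp = _m("BRCA1"), _m("BRCA1/2", start=20)
    prefix_rule([brca1, comp])
    assert brca1.type == MentionType.GENE


def test_abbrev_type_rule():
    long_m = _m("transcriptional intermediary factor 1 family",
                MentionType.FAMILY)
    short_m = _m("TIF1", start=60)
    pair = AbbrPair(short_start=60, short_end=64, short_text="TIF1",
                    long_start=0, long_end=45,
                    long_text="transcriptional intermediary factor 1 family")
    abbrev_type_rule([long_m, short_m], [pair])
    assert short_m.type == MentionType.FAMILY

    # no long-form mention: unchanged
    orphan = _m("XYZ", start=80)
    pair2 = AbbrPair(short_start=80, short_end=83, short_text="XYZ",
                     long_start=70, long_end=75, long_text="xylem")
    abbrev_type_rule([orphan], [pair2])
    assert orphan.type == MentionType.GENE

    # gene-typed long form propagates gene
    er_long = _m("estrogen receptor", MentionType.GENE)
    er_short = _m("ER", start=30)
    er_short.type = MentionType.FAMILY
    pair3 = AbbrPair(short_start=30, short_end=32, short_text="ER",
                     long_start=0, long_end=17,
                     long_text="estrogen receptor")
    abbrev_type_rule([er_long, er_short], [pair3])
    assert er_short.type == MentionType.GENE


def test_majority_rule_worked_example():
    mentions = [
        _m("hif1", MentionType.GENE, start=0),
        _m("hif1", MentionType.GENE, start=10),
        _m("hif1", MentionType.FAMILY, start=20),
        _m("HIF1", MentionType.FAMILY, start=30),
        _m("hif1", MentionType.FAMILY, start=40),
    ]
    majority_rule(mentions)
    assert all(m.type == MentionType.FAMILY for m in mentions)


def test_majority_rule_tie_prefers_gene():
    mentions = [
        _m("ab1", MentionType.GENE, start=0),
        _m("ab1", MentionType.GENE, start=10),
        _m("ab1", MentionType.FAMILY, start=20),
        _m("ab1", MentionType.FAMILY, start=30),
    ]
    majority_rule(mentions)
    assert all(m.type == MentionType.GENE for m in mentions)


def test_majority_rule_single_occurrence_unchanged():
    m = _m("tp53", MentionType.DOMAIN)
    majority_rule([m])
    assert m.type == MentionType.DOMAIN


def test_pipeline_idempotent():
    mentions = [
        _m("TIF1", MentionType.GENE, start=0),
        _m("TIF1alpha", MentionType.GENE, start=10),
        _m("LIM1 domain", MentionType.GENE, start=30),
        _m("OSBP-related proteins", MentionType.GENE, start=50),
        _m("TIF1", MentionType.GENE, start=80),
    ]
    once = apply_typing_rules(copy.deepcopy(mentions))
    twice = apply_typing_rules(copy.deepcopy(once))
    assert [(m.text, m.type) for m in once] == \
           [(m.text, m.type) for m in twice]


def test_rules_never_change_spans():
    mentions = [
        _m("TIF1", MentionType.GENE, start=0),
        _m("TIF1alpha", MentionType.GENE, start=10),
        _m("X kinase domain", MentionType.GENE, start=30),
    ]
    before = [(m.start, m.end, m.text) for m in mentions]
    apply_typing_rules(mentions)
    assert [(m.start, m.end, m.text) for m in mentions] == before
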