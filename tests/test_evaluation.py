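"""Precision / recall / F-measure and the error taxonomy."""

import pytest

from genenorm.evaluation import (ERROR_CATEGORIES, docid_prf,
                                 error_breakdown, mention_prf)
from genenorm.normalizer import LexiconEntry, build_index
from genenorm.types import Document, Mention, MentionType


def _m(start, end, typ=MentionType.GENE, text="x"):
    return Mention(start=start, end=end, text=text, type=typ)


def test_perfect_prediction():
    gold = {"d1": [_m(0, 5), _m(10, 15, MentionType.FAMILY)]}
    prf = mention_prf(gold, gold, mode="strict")
    assert (prf.precision, prf.recall, prf.f1) == (1.0, 1.0, 1.0)


def test_hand_computed_counts():
    gold = {"d": [_m(0, 5), _m(10, 15), _m(20, 25), _m(30, 35)]}
    pred = {"d": [_m(0, 5), _m(10, 15), _m(20, 25), _m(40, 45),
                  _m(50, 55)]}
    prf = mention_prf(gold, pred, mode="strict")
    assert prf.precision == pytest.approx(0.6)
    assert prf.recall == pytest.approx(0.75)
    assert prf.f1 == pytest.approx(2 * 0.6 * 0.75 / 1.35)


def test_empty_prediction_convention():
    gold = {"d": [_m(0, 5)]}
    prf = mention_prf(gold, {"d": []}, mode="strict")
    assert prf.precision == 0.0 and prf.recall == 0.0 and prf.f1 == 0.0
    assert prf.undefined


def test_overlap_mode_and_type_requirement():
    gold = {"d": [_m(0, 10)]}
    assert mention_prf(gold, {"d": [_m(3, 7)]}, mode="overlap").f1 == 1.0
    assert mention_prf(gold, {"d": [_m(3, 7)]}, mode="strict").f1 == 0.0
    off_type = {"d": [_m(3, 7, MentionType.FAMILY)]}
    assert mention_prf(gold, off_type, mode="overlap").f1 == 0.0


def test_per_type_breakdown():
    gold = {"d": [_m(0, 5), _m(10, 15, MentionType.FAMILY)]}
    pred = {"d": [_m(0, 5)]}
    prf = mention_prf(gold, pred, mode="strict", by_type=True)
    assert prf.per_type["Gene"].f1 == 1.0
    assert prf.per_type["FamilyName"].recall == 0.0


def test_metrics_invariant_under_document_reordering():
    gold = {"a": [_m(0, 5)], "b": [_m(0, 5), _m(6, 9)]}
    pred = {"b": [_m(0, 5)], "a": [_m(0, 5)]}
    assert mention_prf(gold, pred).f1 == \
        mention_prf(dict(reversed(gold.items())), pred).f1


def test_duplicate_doc_ids_rejected():
    d = Document(doc_id="1", title="t", abstract="a")
    with pytest.raises(ValueError):
        mention_prf([d, d], [d, d])


def test_docid_examples():
    assert docid_prf({"d": {"a", "b"}}, {"d": {"a", "b"}}).f1 == 1.0
    prf = docid_prf({"d": {"a", "b"}}, {"d": {"b", "c"}})
    assert (prf.precision, prf.recall, prf.f1) == (0.5, 0.5, 0.5)
    sup = docid_prf({"d": {"a"}}, {"d": {"a", "b"}})
    assert sup.recall == 1.0 and sup.precision < 1.0


def _doc(doc_id, mentions, ids=()):
    d = Document(doc_id=doc_id, title="title here", abstract="abstract here")
    d.mentions = mentions
    d.doc_ids = set(ids)
    return d


def test_error_breakdown_categories_and_partition():
    idx = build_index([
        LexiconEntry("1", "9606", ("title",)),
        LexiconEntry("2", "10090", ("mouse gene",)),
        LexiconEntry("3", "9606", ("absent name",)),
    ])
    gold = [_doc("d", [_m(0, 5, MentionType.GENE, "title")], ids={"1", "3"})]
    pred = [_doc("d", [_m(0, 5, MentionType.FAMILY, "title"),
                       _m(6, 10, MentionType.GENE, "here")],
                 ids={"2"})]
    counts = error_breakdown(gold, pred, idx)
    assert set(counts) == set(ERROR_CATEGORIES)
    assert counts["type_confusion"] >= 2  # the FP and the matching FN
    assert counts["nonhuman"] == 1        # predicted mouse-only id
    assert counts["dictionary_insufficiency"] == 1  # id 3 unreachable
    # partition: mention FP+FN plus id FP+FN
    m = mention_prf(gold, pred, mode="strict")
    i = docid_prf(gold, pred)
    assert sum(counts.values()) == m.fp + m.fn + i.fp + i.fn
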