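"""Mention-level and document-level precision / recall / F-measure.

All metrics are micro-averaged (the BioCreative convention). Strict
mention matching requires identical (start, end, type); overlap matching
requires span intersection with equal type. Zero-denominator metrics
report 0 with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .normalizer import LexiconIndex, normalize_name
from .types import Document, Mention, MentionType


@dataclass
class PRF:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    undefined: bool = False
    per_type: dict = field(default_factory=dict)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float, bool]:
    undefined = (tp + fp == 0) or (tp + fn == 0)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f, undefined


def _as_mention_map(docs) -> dict[str, list[Mention]]:
    if isinstance(docs, dict):
        return docs
    out: dict[str, list[Mention]] = {}
    for d in docs:
        if d.doc_id in out:
            raise ValueError(f"duplicate doc id {d.doc_id}")
        out[d.doc_id] = list(d.mentions)
    return out


def _match_counts(gold: list[Mention], pred: list[Mention],
                  mode: str) -> tuple[int, int, int]:
    if mode == "strict":
        gold_keys = [(m.start, m.end, m.type) for m in gold]
        tp = 0
        remaining = list(gold_keys)
        for m in pred:
            key = (m.start, m.end, m.type)
            if key in remaining:
                remaining.remove(key)
                tp += 1
        return tp, len(pred) - tp, len(gold) - tp
    if mode != "overlap":
        raise ValueError(f"unknown mode {mode!r}")
    unmatched = list(gold)
    tp = 0
    for m in sorted(pred, key=lambda x: (x.start, x.end)):
        hit = next((g for g in unmatched
                    if g.type == m.type and g.start < m.end
                    and m.start < g.end), None)
        if hit is not None:
            unmatched.remove(hit)
            tp += 1
    return tp, len(pred) - tp, len(gold) - tp


def mention_prf(gold, pred, mode: str = "strict",
                by_type: bool = False) -> PRF:
    """Micro-averaged mention-level metrics over a document collection."""
    gold_map = _as_mention_map(gold)
    pred_map = _as_mention_map(pred)
    tp = fp = fn = 0
    for doc_id in sorted(set(gold_map) | set(pred_map)):
        g = gold_map.get(doc_id, [])
        p = pred_map.get(doc_id, [])
        t, f_p, f_n = _match_counts(g, p, mode)
        tp, fp, fn = tp + t, fp + f_p, fn + f_n
    prec, rec, f1, undef = _prf(tp, fp, fn)
    result = PRF(prec, rec, f1, tp, fp, fn, undef)
    if by_type:
        for typ in MentionType:
            sub = mention_prf(
                {k: [m for m in v if m.type == typ]
                 for k, v in gold_map.items()},
                {k: [m for m in v if m.type == typ]
                 for k, v in pred_map.items()},
                mode=mode)
            result.per_type[typ.value] = sub
    return result


def _as_id_map(docs) -> dict[str, set[str]]:
    if isinstance(docs, dict):
        return {k: set(v) for k, v in docs.items()}
    out = {}
    for d in docs:
        if d.doc_id in out:
            raise ValueError(f"duplicate doc id {d.doc_id}")
        out[d.doc_id] = set(d.doc_ids)
    return out


def docid_prf(gold, pred) -> PRF:
    """Micro-averaged document-level identifier metrics over (doc, id)
    pairs."""
    gold_map = _as_id_map(gold)
    pred_map = _as_id_map(pred)
    tp = fp = fn = 0
    for doc_id in sorted(set(gold_map) | set(pred_map)):
        g = gold_map.get(doc_id, set())
        p = pred_map.get(doc_id, set())
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    prec, rec, f1, undef = _prf(tp, fp, fn)
    return PRF(prec, rec, f1, tp, fp, fn, undef)


# ------------------------------------------------------------ error taxonomy

ERROR_CATEGORIES = (
    "type_confusion",          # same span, different type
    "boundary_or_missed",      # overlapping or absent span
    "not_a_gene",              # FP span unknown to the lexicon
    "wrong_id_ambiguity",      # id confused with a same-named gene
    "dictionary_insufficiency",  # gold id unreachable through the lexicon
    "not_in_gold",             # predicted id/mention absent from gold
    "nonhuman",                # predicted id of another species
    "other",
)


def error_breakdown(gold_docs: list[Document], pred_docs: list[Document],
                    index: LexiconIndex | None = None,
                    default_taxid: str = "9606") -> dict[str, int]:
    """Assign every mention-level and id-level FP/FN to one category.

    The decision tree is documented in order: mention FPs — same-span
    different-type gold (type confusion), overlapping gold (boundary),
    text absent from the lexicon (not a gene), otherwise not-in-gold;
    mention FNs — overlapped by a prediction of another type (type
    confusion), otherwise boundary/missed. Id-level FPs — wrong species
    (nonhuman), a name shared with a gold id's entry (ambiguity), else
    not-in-gold; id FNs — no lexicon name for the id appears in the text
    (dictionary insufficiency), a name shared with a predicted id
    (ambiguity), else other. Category counts always sum to FP + FN.
    """
    counts = {c: 0 for c in ERROR_CATEGORIES}
    gold_by_id = {d.doc_id: d for d in gold_docs}
    pred_by_id = {d.doc_id: d for d in pred_docs}

    for doc_id in sorted(set(gold_by_id) | set(pred_by_id)):
        g_doc = gold_by_id.get(doc_id)
        p_doc = pred_by_id.get(doc_id)
        g_mentions = g_doc.mentions if g_doc else []
        p_mentions = p_doc.mentions if p_doc else []
        g_keys = {(m.start, m.end, m.type) for m in g_mentions}
        p_keys = {(m.start, m.end, m.type) for m in p_mentions}

        for m in p_mentions:  # mention-level FPs
            if (m.start, m.end, m.type) in g_keys:
                continue
            if any(g.start == m.start and g.end == m.end
                   for g in g_mentions):
                counts["type_confusion"] += 1
            elif any(g.overlaps(m.start, m.end) for g in g_mentions):
                counts["boundary_or_missed"] += 1
            elif index is not None and not exactable(m.text, index):
                counts["not_a_gene"] += 1
            else:
                counts["not_in_gold"] += 1
        for m in g_mentions:  # mention-level FNs
            if (m.start, m.end, m.type) in p_keys:
                continue
            if any(p.overlaps(m.start, m.end) and p.type != m.type
                   for p in p_mentions):
                counts["type_confusion"] += 1
            else:
                counts["boundary_or_missed"] += 1

        g_ids = set(g_doc.doc_ids) if g_doc else set()
        p_ids = set(p_doc.doc_ids) if p_doc else set()
        text = (g_doc or p_doc).text
        for gid in sorted(p_ids - g_ids):  # id-level FPs
            entry = index.entries.get(gid) if index else None
            if entry is not None and entry.taxid != default_taxid:
                counts["nonhuman"] += 1
            elif entry is not None and _shares_name(gid, g_ids, index):
                counts["wrong_id_ambiguity"] += 1
            else:
                counts["not_in_gold"] += 1
        for gid in sorted(g_ids - p_ids):  # id-level FNs
            entry = index.entries.get(gid) if index else None
            if entry is not None and not _name_in_text(entry, text):
                counts["dictionary_insufficiency"] += 1
            elif entry is not None and _shares_name(gid, p_ids, index):
                counts["wrong_id_ambiguity"] += 1
            else:
                counts["other"] += 1
    return counts


def exactable(text: str, index: LexiconIndex) -> bool:
    return normalize_name(text) in index.exact


def _shares_name(gid: str, other_ids: set[str],
                 index: LexiconIndex) -> bool:
    names = {normalize_name(n) for n in index.entries[gid].names}
    for other in other_ids:
        entry = index.entries.get(other)
        if entry and names & {normalize_name(n) for n in entry.names}:
            return True
    return False


def _name_in_text(entry, text: str) -> bool:
    low = normalize_name(text)
    return any(normalize_name(n) in low for n in entry.names)
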