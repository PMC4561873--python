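"""BIEO sequence tagging of gene, gene-family and protein-domain mentions.

Each token receives one of ten labels: B/I/E (begin, inside, end) crossed
with the three entity types, plus O (outside). A single joint model emits
all three types; single-token mentions are labeled B. Decoded label
sequences pass through a repair step that rewrites structurally invalid
transitions before mentions are assembled.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .crf import CRFConfig, LinearChainCRF
from .features import (SemanticLexiconSet, TEMPLATE_VERSION, encode_features,
                       extract_features)
from .lingua import POS_TAGGER_NAME, STEMMER_NAME
from .tokenizer import sentence_tokens
from .types import Document, Mention, MentionType, Token

LABELS = ["O"] + [f"{b}-{t.value}" for t in MentionType for b in "BIE"]
_LABEL_TO_ID = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class TaggerConfig:
    crf: CRFConfig = field(default_factory=CRFConfig)
    min_train_recall: float = 0.9  # sanity floor for training-set recall


@dataclass
class TaggerModel:
    """A trained CRF plus everything needed to reproduce its features."""

    crf: LinearChainCRF
    feature_names: list[str]
    labels: list[str]
    template_version: str
    lexicon_fingerprint: str
    config: dict

    def save(self, path) -> None:
        meta = json.dumps({
            "labels": self.labels,
            "template_version": self.template_version,
            "lexicon_fingerprint": self.lexicon_fingerprint,
            "config": self.config,
        })
        state = self.crf.get_state()
        crf_config = json.dumps(state.pop("config"))
        np.savez_compressed(
            path, meta=np.array(meta), crf_config=np.array(crf_config),
            feature_names=np.array(self.feature_names, dtype=object),
            **{k: np.asarray(v) for k, v in state.items()},
        )

    @classmethod
    def load(cls, path) -> "TaggerModel":
        with np.load(path, allow_pickle=True) as data:
            meta = json.loads(str(data["meta"]))
            state = {k: data[k] for k in data.files
                     if k not in ("meta", "crf_config", "feature_names")}
            state["config"] = json.loads(str(data["crf_config"]))
            crf = LinearChainCRF.from_state(state)
            names = [str(x) for x in data["feature_names"]]
        return cls(crf=crf, feature_names=names, labels=meta["labels"],
                   template_version=meta["template_version"],
                   lexicon_fingerprint=meta["lexicon_fingerprint"],
                   config=meta["config"])


def lexicon_fingerprint(lexicons: SemanticLexiconSet) -> str:
    h = hashlib.sha256()
    for name in ("gene_vocab", "gene_context", "disease", "chemical",
                 "domain", "cell", "protein_symbol"):
        for entry in sorted(getattr(lexicons, name)):
            h.update(entry.encode("utf-8"))
        h.update(b"\x00")
    return h.hexdigest()[:16]


def _mentions_to_labels(tokens: list[Token], mentions: list[Mention],
                        doc_id: str) -> list[str]:
    """Project gold mention spans onto token labels, snapping misaligned
    spans outward to token boundaries (with a warning)."""
    labels = ["O"] * len(tokens)
    for m in mentions:
        covered = [i for i, t in enumerate(tokens)
                   if t.start < m.end and m.start < t.end]
        if not covered:
            continue
        i0, i1 = covered[0], covered[-1]
        if tokens[i0].start != m.start or tokens[i1].end != m.end:
            warnings.warn(
                f"{doc_id}: mention {m.text!r} ({m.start},{m.end}) snapped "
                f"to token boundaries ({tokens[i0].start},{tokens[i1].end})",
                stacklevel=2,
            )
        if i0 == i1:
            labels[i0] = f"B-{m.type.value}"
        else:
            labels[i0] = f"B-{m.type.value}"
            labels[i1] = f"E-{m.type.value}"
            for k in range(i0 + 1, i1):
                labels[k] = f"I-{m.type.value}"
    return labels


def _doc_sentence_features(doc: Document,
                           lexicons: SemanticLexiconSet
                           ) -> list[tuple[list[Token], list[dict]]]:
    text = doc.text
    out = []
    for toks in sentence_tokens(text):
        out.append((toks, extract_features(toks, lexicons, doc.abbrev_pairs)))
    return out


def train(corpus: list[Document], lexicons: SemanticLexiconSet | None = None,
          config: TaggerConfig | None = None) -> TaggerModel:
    """Train the joint three-type tagger on annotated documents.

    Raises on an empty corpus or a corpus with no positive labels. Gene
    mentions carrying multiple ids (composites) train like any other span.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    lexicons = lexicons if lexicons is not None else SemanticLexiconSet.default()
    config = config or TaggerConfig()

    feature_index: dict[str, int] = {}
    X: list[list[list[int]]] = []
    y: list[list[int]] = []
    # first pass: collect encoded features so the vocabulary is sorted and
    # therefore independent of document order
    raw_sents: list[tuple[list[list[str]], list[int]]] = []
    n_positive = 0
    for doc in corpus:
        for toks, feats in _doc_sentence_features(doc, lexicons):
            if not toks:
                continue
            labels = _mentions_to_labels(toks, doc.mentions, doc.doc_id)
            n_positive += sum(1 for lab in labels if lab != "O")
            raw_sents.append(
                ([encode_features(f) for f in feats],
                 [_LABEL_TO_ID[lab] for lab in labels])
            )
    if n_positive == 0:
        raise ValueError("training corpus contains no positive labels")
    all_feats = sorted({f for sent, _ in raw_sents for tok in sent for f in tok})
    feature_index = {f: i for i, f in enumerate(all_feats)}
    for sent, labels in raw_sents:
        X.append([[feature_index[f] for f in tok] for tok in sent])
        y.append(labels)

    crf = LinearChainCRF(len(LABELS), len(feature_index), config.crf)
    stats = crf.fit(X, y)
    return TaggerModel(
        crf=crf,
        feature_names=all_feats,
        labels=LABELS,
        template_version=TEMPLATE_VERSION,
        lexicon_fingerprint=lexicon_fingerprint(lexicons),
        config={
            "crf": stats | {"order": config.crf.order, "l2": config.crf.l2,
                            "max_iter": config.crf.max_iter},
            "stemmer": STEMMER_NAME,
            "pos_tagger": POS_TAGGER_NAME,
        },
    )


def decode(model: TaggerModel, features: list[dict],
           template_version: str = TEMPLATE_VERSION) -> list[str]:
    """Decode one sentence's feature maps to a repaired label sequence."""
    if template_version != model.template_version:
        raise ValueError(
            f"feature template {template_version!r} does not match model "
            f"template {model.template_version!r}"
        )
    index = getattr(model, "_feature_index", None)
    if index is None:
        index = {f: i for i, f in enumerate(model.feature_names)}
        model._feature_index = index
    encoded = [
        [index[f] for f in encode_features(feats) if f in index]
        for feats in features
    ]
    ids = model.crf.decode(encoded)
    return repair_labels([model.labels[i] for i in ids])


def repair_labels(labels: list[str]) -> list[str]:
    """Rewrite a raw label sequence into a structurally valid one.

    Leading I becomes B; an E with no open block becomes B; type conflicts
    inside one B..E block resolve to the type of the block's B. Idempotent.
    """
    out: list[str] = []
    open_type: str | None = None
    for lab in labels:
        if lab == "O":
            out.append("O")
            open_type = None
            continue
        tag, typ = lab.split("-", 1)
        if tag == "B":
            out.append(lab)
            open_type = typ
        elif tag == "I":
            if open_type is None:
                out.append(f"B-{typ}")
                open_type = typ
            else:
                out.append(f"I-{open_type}")
        else:  # E
            if open_type is None:
                out.append(f"B-{typ}")
                open_type = typ
            else:
                out.append(f"E-{open_type}")
                open_type = None
    return out


def labels_to_mentions(labels: list[str], tokens: list[Token],
                       text: str) -> list[Mention]:
    """Assemble maximal B(..I..)E / lone-B blocks into mentions."""
    mentions: list[Mention] = []
    i = 0
    n = len(labels)
    while i < n:
        lab = labels[i]
        if lab == "O":
            i += 1
            continue
        tag, typ = lab.split("-", 1)
        j = i
        if tag in ("B", "I", "E"):
            # extend through I of the same type, optionally closing at E
            while j + 1 < n:
                nxt = labels[j + 1]
                if nxt == f"I-{typ}":
                    j += 1
                elif nxt == f"E-{typ}":
                    j += 1
                    break
                else:
                    break
        start, end = tokens[i].start, tokens[j].end
        mentions.append(Mention(start=start, end=end, text=text[start:end],
                                type=MentionType(typ), source="crf"))
        i = j + 1
    return mentions


def tag_document(model: TaggerModel, doc: Document,
                 lexicons: SemanticLexiconSet | None = None) -> list[Mention]:
    """Run the tagger over a whole document and return its mentions."""
    lexicons = lexicons if lexicons is not None else SemanticLexiconSet.default()
    text = doc.text
    mentions: list[Mention] = []
    for toks, feats in _doc_sentence_features(doc, lexicons):
        if not toks:
            continue
        labels = decode(model, feats)
        mentions.extend(labels_to_mentions(labels, toks, text))
    return mentions
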