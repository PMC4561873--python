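"""Gene normalization: mapping typed gene mentions to concept identifiers.

Two matching strategies run against a gene lexicon. Exact match compares
names after normalization (lowercase, spaces and hyphens removed, Greek
letters spelled out), so "ESR-1", "ESR1" and "esr1" are the same key.
Bag-of-words match scores the cosine similarity between ln-scaled
inverse-name-frequency token vectors of the mention and of each candidate
name; a mention token's weight is w(t) = ln(1 + N/df(t)), with N the number
of lexicon entries and df(t) the number of entries containing t, term
frequency capped at one. An entry's score is its best-scoring single name.

Candidates are then re-ranked with document context: a candidate gains a
bonus when a family-name mention in the document matches its family terms
or full name, and likewise for protein-domain mentions against its domain
terms — the family/domain-assisted disambiguation that separates, e.g., the
two genes named TEL1 when the text mentions the PNT domain. Family and
domain mentions themselves are never normalized to gene identifiers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from . import composite
from .lingua import porter_stem
from .tokenizer import tokenize
from .types import AbbrPair, Document, Mention, MentionType, expand_greek


@dataclass(frozen=True)
class LexiconEntry:
    """One gene concept: identifier, species, names and optional
    family/domain association terms."""

    gene_id: str
    taxid: str
    names: tuple[str, ...]
    family_terms: tuple[str, ...] = ()
    domain_terms: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.names:
            raise ValueError(f"entry {self.gene_id}: names must be non-empty")


@dataclass
class NormalizerConfig:
    bow_threshold: float = 0.6     # θ: minimum bag-of-words score
    family_bonus: float = 0.2      # β_f
    domain_bonus: float = 0.3      # β_d
    context_threshold: float = 0.5  # minimum context-term match score
    default_taxid: str = "9606"


@dataclass
class Candidate:
    gene_id: str
    score: float
    strategy: str  # "exact" | "bow"
    taxid: str


@dataclass
class NormalizationResult:
    """Ranked candidates per Gene mention plus the document identifier set
    (the union of top-ranked ids of Gene mentions; family/domain mentions
    contribute none)."""

    mention_candidates: list[tuple[Mention, list[Candidate]]]
    doc_ids: set[str] = field(default_factory=set)


def normalize_name(name: str) -> str:
    """Exact-match key: Greek spelled out, lowercased, spaces/hyphens gone."""
    return re.sub(r"[\s\-–]+", "", expand_greek(name).lower())


def name_tokens(name: str) -> list[str]:
    """Stemmed lowercase alphanumeric tokens of a name."""
    return [porter_stem(t.text.lower())
            for t in tokenize(expand_greek(name))
            if any(c.isalnum() for c in t.text)]


def _id_key(gene_id: str):
    return (0, int(gene_id)) if gene_id.isdigit() else (1, gene_id)


class LexiconIndex:
    """Exact-match map plus an inverted token index with IDF-style weights."""

    def __init__(self, entries: list[LexiconEntry]):
        if not entries:
            raise ValueError("empty lexicon")
        seen = set()
        for e in entries:
            if e.gene_id in seen:
                raise ValueError(f"duplicate gene_id {e.gene_id}")
            seen.add(e.gene_id)
        self.entries = {e.gene_id: e for e in entries}
        self.exact: dict[str, list[str]] = {}
        df: dict[str, int] = {}
        self._name_tokens: dict[str, list[list[str]]] = {}
        for e in entries:
            entry_tokens = set()
            toklists = []
            for name in e.names:
                self.exact.setdefault(normalize_name(name), [])
                key = normalize_name(name)
                if e.gene_id not in self.exact[key]:
                    self.exact[key].append(e.gene_id)
                toks = name_tokens(name)
                toklists.append(toks)
                entry_tokens.update(toks)
            self._name_tokens[e.gene_id] = toklists
            for t in entry_tokens:
                df[t] = df.get(t, 0) + 1
        self.N = len(entries)
        self.weights = {t: math.log(1 + self.N / c) for t, c in df.items()}
        self.inverted: dict[str, set[str]] = {}
        for e in entries:
            for toks in self._name_tokens[e.gene_id]:
                for t in toks:
                    self.inverted.setdefault(t, set()).add(e.gene_id)
        self._unseen_weight = math.log(1 + self.N)

    def weight(self, token: str) -> float:
        return self.weights.get(token, self._unseen_weight)

    def all_names(self) -> set[str]:
        return {n for e in self.entries.values() for n in e.names}


def build_index(entries: list[LexiconEntry]) -> LexiconIndex:
    return LexiconIndex(entries)


def _taxid_soft_filter(candidates: list[str], index: LexiconIndex,
                       taxid: str | None) -> list[str]:
    """Keep candidates of the assigned species, unless that empties a
    non-empty list (homologs of other species are then retained)."""
    if taxid is None or not candidates:
        return candidates
    kept = [c for c in candidates if index.entries[c].taxid == taxid]
    return kept if kept else candidates


def exact_match(mention_text: str, index: LexiconIndex,
                taxid: str | None = None) -> list[str]:
    """Gene ids whose names normalize to the mention's normalized text."""
    ids = index.exact.get(normalize_name(mention_text), [])
    return sorted(_taxid_soft_filter(list(ids), index, taxid), key=_id_key)


def bow_score(mention_text: str, entry: LexiconEntry,
              index: LexiconIndex) -> float:
    """Cosine similarity between the mention and the entry's best name."""
    m_toks = set(name_tokens(mention_text))
    if not m_toks:
        return 0.0
    m_norm = math.sqrt(sum(index.weight(t) ** 2 for t in m_toks))
    best = 0.0
    for toks in index._name_tokens.get(entry.gene_id,
                                       [name_tokens(n) for n in entry.names]):
        n_toks = set(toks)
        if not n_toks:
            continue
        shared = m_toks & n_toks
        if not shared:
            continue
        n_norm = math.sqrt(sum(index.weight(t) ** 2 for t in n_toks))
        score = sum(index.weight(t) ** 2 for t in shared) / (m_norm * n_norm)
        best = max(best, score)
    return best


def bow_candidates(mention_text: str, index: LexiconIndex,
                   taxid: str | None = None,
                   threshold: float = 0.6) -> list[Candidate]:
    """All entries scoring at least ``threshold``, best first (ties by
    numerically smaller gene id)."""
    pool: set[str] = set()
    for t in set(name_tokens(mention_text)):
        pool |= index.inverted.get(t, set())
    scored = []
    for gid in pool:
        s = bow_score(mention_text, index.entries[gid], index)
        if s >= threshold:
            scored.append(Candidate(gene_id=gid, score=s, strategy="bow",
                                    taxid=index.entries[gid].taxid))
    ids = _taxid_soft_filter([c.gene_id for c in scored], index, taxid)
    scored = [c for c in scored if c.gene_id in ids]
    scored.sort(key=lambda c: (-c.score, _id_key(c.gene_id)))
    return scored


def _context_match(context_texts: list[str], terms: tuple[str, ...],
                   index: LexiconIndex, threshold: float) -> bool:
    """Does any context mention bag-of-words-match any of the terms?"""
    strip = {"family", "families", "proteins", "protein", "domain",
             "domains", "motif", "motifs", "subfamily", "superfamily"}
    for ctx in context_texts:
        c_toks = {t for t in name_tokens(ctx) if t not in strip}
        if not c_toks:
            continue
        c_norm = math.sqrt(sum(index.weight(t) ** 2 for t in c_toks))
        for term in terms:
            t_toks = {t for t in name_tokens(term) if t not in strip}
            if not t_toks:
                continue
            shared = c_toks & t_toks
            if not shared:
                continue
            t_norm = math.sqrt(sum(index.weight(t) ** 2 for t in t_toks))
            score = (sum(index.weight(t) ** 2 for t in shared)
                     / (c_norm * t_norm))
            if score >= threshold:
                return True
    return False


def disambiguate(candidates: list[Candidate], index: LexiconIndex,
                 family_context: list[str] = (),
                 domain_context: list[str] = (),
                 config: NormalizerConfig | None = None) -> list[Candidate]:
    """Re-rank candidates using family/domain mentions from the document."""
    config = config or NormalizerConfig()
    rescored = []
    for c in candidates:
        entry = index.entries[c.gene_id]
        bonus = 0.0
        if family_context and (entry.family_terms or entry.names):
            targets = entry.family_terms + entry.names
            if _context_match(list(family_context), targets, index,
                              config.context_threshold):
                bonus += config.family_bonus
        if domain_context and entry.domain_terms:
            if _context_match(list(domain_context), entry.domain_terms,
                              index, config.context_threshold):
                bonus += config.domain_bonus
        rescored.append(Candidate(gene_id=c.gene_id, score=c.score + bonus,
                                  strategy=c.strategy, taxid=c.taxid))
    rescored.sort(key=lambda c: (-c.score, _id_key(c.gene_id)))
    return rescored


def normalize_mention_text(text: str, index: LexiconIndex,
                           taxid: str | None,
                           family_context: list[str],
                           domain_context: list[str],
                           config: NormalizerConfig) -> list[Candidate]:
    ids = exact_match(text, index, taxid)
    if ids:
        cands = [Candidate(gene_id=g, score=1.0, strategy="exact",
                           taxid=index.entries[g].taxid) for g in ids]
    else:
        cands = bow_candidates(text, index, taxid, config.bow_threshold)
    if not cands:
        return []
    return disambiguate(cands, index, family_context, domain_context, config)


def normalize_document(doc: Document, index: LexiconIndex,
                       config: NormalizerConfig | None = None
                       ) -> NormalizationResult:
    """Resolve every Gene mention of ``doc`` to concept identifiers.

    Composite mentions are expanded first and each constituent resolved
    separately; a short-form mention whose long form resolved takes the
    long form's candidate. The document id set is the union of top-ranked
    ids over Gene mentions.
    """
    config = config or NormalizerConfig()
    family_context = [m.text for m in doc.mentions
                      if m.type == MentionType.FAMILY]
    domain_context = [m.text for m in doc.mentions
                      if m.type == MentionType.DOMAIN]

    per_mention: list[tuple[Mention, list[Candidate]]] = []
    resolved: dict[int, list[Candidate]] = {}
    for i, m in enumerate(doc.mentions):
        if m.type != MentionType.GENE:
            continue
        taxid = m.taxid or config.default_taxid
        constituents = composite.expand(m.text)
        top_ids: list[str] = []
        ranked_all: list[Candidate] = []
        for text in constituents:
            ranked = normalize_mention_text(
                text, index, taxid, family_context, domain_context, config)
            ranked_all.extend(ranked)
            if ranked:
                top_ids.append(ranked[0].gene_id)
        m.ids = top_ids
        resolved[i] = ranked_all
        per_mention.append((m, ranked_all))

    # abbreviation override: the long form's candidate wins for short forms
    for pair in doc.abbrev_pairs:
        long_ids: list[str] = []
        for i, m in enumerate(doc.mentions):
            if (m.type == MentionType.GENE and m.ids
                    and m.overlaps(pair.long_start, pair.long_end)):
                long_ids = m.ids
                break
        if not long_ids:
            continue
        for i, m in enumerate(doc.mentions):
            if (m.type == MentionType.GENE and m.text == pair.short_text
                    and m.ids != long_ids):
                m.ids = list(long_ids)

    doc_ids = {gid for m in doc.mentions
               if m.type == MentionType.GENE for gid in m.ids}
    doc.doc_ids = doc_ids
    return NormalizationResult(mention_candidates=per_mention,
                               doc_ids=doc_ids)


# ------------------------------------------------------------- lexicon I/O

LEXICON_HEADER = "gene_id\ttaxid\tnames\tfamily_terms\tdomain_terms"


def read_gene_lexicon(path) -> list[LexiconEntry]:
    """Gene lexicon TSV: header line, then one row per concept with
    pipe-separated names/family_terms/domain_terms."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != LEXICON_HEADER:
            raise ValueError(f"bad lexicon header: {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"line {lineno}: expected 5 columns")
            gene_id, taxid, names, fam, dom = parts
            entries.append(LexiconEntry(
                gene_id=gene_id, taxid=taxid,
                names=tuple(n for n in names.split("|") if n),
                family_terms=tuple(t for t in fam.split("|") if t),
                domain_terms=tuple(t for t in dom.split("|") if t),
            ))
    return entries


def write_gene_lexicon(entries: list[LexiconEntry], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(LEXICON_HEADER + "\n")
        for e in entries:
            fh.write("\t".join([
                e.gene_id, e.taxid, "|".join(e.names),
                "|".join(e.family_terms), "|".join(e.domain_terms),
            ]) + "\n")
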